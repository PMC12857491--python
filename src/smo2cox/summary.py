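"""Cohort-level aggregation of per-trial plateau determinations.

Produces the study-style outputs: plateau counts and percentages per
muscle x condition group per criterion, a trials x methods comparison grid
with pairwise percent agreement, and pointwise mean +/- SD group kinetics.

Counts are the authoritative quantity; percentages are stored at full float
precision and formatting is left to the caller (printed tables elsewhere may
truncate repeating decimals, e.g. 29/30 shown as 96.66).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import percent_agreement
from .trace import SmO2Trace

GROUP_COLS = ["criterion_id", "muscle", "condition"]


class SummaryError(ValueError):
    pass


def determinations_frame(per_trial: list[dict]) -> pd.DataFrame:
    """Normalize a list of per-trial record dicts into a tidy frame.

    Each record needs keys: subject_id, muscle, condition, criterion_id,
    detected (bool). Enum values are stored as their string names.
    """
    df = pd.DataFrame(per_trial)
    for col in ("muscle", "condition"):
        if col in df.columns:
            df[col] = df[col].map(
                lambda x: x.value if hasattr(x, "value") else x
            )
    return df


def summarize_cohort(determinations: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of plateau-positive trials per group.

    Input: tidy frame with columns subject_id, muscle, condition,
    criterion_id, detected. Output: one row per (criterion_id, muscle,
    condition) with n_total, n_plateau, pct_plateau; pct is NaN for an empty
    group.
    """
    if determinations.empty:
        return pd.DataFrame(
            columns=GROUP_COLS + ["n_total", "n_plateau", "pct_plateau"]
        )
    missing = set(GROUP_COLS + ["detected"]) - set(determinations.columns)
    if missing:
        raise SummaryError(f"determinations frame missing columns {missing}")
    g = determinations.groupby(GROUP_COLS, sort=True)["detected"]
    out = g.agg(n_total="size", n_plateau="sum").reset_index()
    out["n_plateau"] = out["n_plateau"].astype(int)
    out["pct_plateau"] = np.where(
        out["n_total"] > 0, 100.0 * out["n_plateau"] / out["n_total"], np.nan
    )
    return out


@dataclass
class ComparisonMatrix:
    """Trials x methods binary grid plus pairwise percent agreement."""

    grid: pd.DataFrame  # index: trial ids; columns: method ids; bool
    agreement: pd.DataFrame  # methods x methods, percent, 100 on diagonal


def build_comparison_matrix(
    determinations_by_method: dict[str, pd.Series],
) -> ComparisonMatrix:
    """Assemble aligned per-trial binary vectors from several methods.

    Methods are threshold criteria (A5, A10, R5, R10) and/or rater-consensus
    vectors; all must be indexed by the same trial identifiers.
    """
    if not determinations_by_method:
        raise SummaryError("no methods provided")
    grid = pd.DataFrame(determinations_by_method)
    if grid.isna().any().any():
        raise SummaryError(
            "misaligned trial identifiers across methods: "
            f"{grid.index[grid.isna().any(axis=1)].tolist()}"
        )
    grid = grid.astype(bool)
    methods = list(grid.columns)
    agreement = pd.DataFrame(
        100.0, index=methods, columns=methods, dtype=float
    )
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            pct = percent_agreement(grid[a], grid[b])
            agreement.loc[a, b] = pct
            agreement.loc[b, a] = pct
    return ComparisonMatrix(grid=grid, agreement=agreement)


def mean_sd_kinetics(traces: list[SmO2Trace]) -> pd.DataFrame:
    """Pointwise mean and sample SD (n-1 denominator) of aligned 1-Hz traces.

    All traces must share the identical time grid (resample first). SD is NaN
    when fewer than 2 traces are supplied.
    """
    if not traces:
        raise SummaryError("no traces provided")
    grid = traces[0].times
    for t in traces[1:]:
        if len(t.times) != len(grid) or not np.array_equal(t.times, grid):
            raise SummaryError(
                f"trace {t.subject_id} is not on the common time grid"
            )
    stack = np.vstack([t.values for t in traces])
    mean = stack.mean(axis=0)
    sd = (
        stack.std(axis=0, ddof=1)
        if len(traces) >= 2
        else np.full(len(grid), np.nan)
    )
    return pd.DataFrame({"time_s": grid, "mean": mean, "sd": sd})
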