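"""Reading and writing per-trial SmO2 CSV files and cohort manifests.

The canonical per-trial format is a two-column UTF-8 CSV with header
``time_s,smo2_pct``. Vendor exports vary across firmware versions, so
:class:`ColumnMap` lets callers point at differently named (or positional)
columns instead of editing files.

A cohort is described by a manifest (CSV or YAML) with columns
``path,subject_id,muscle,condition``; paths are resolved relative to the
manifest's own directory.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trace import Condition, Muscle, SmO2Trace, TraceValidationError

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


class SignalIOError(ValueError):
    """A trial file or manifest could not be read as valid SmO2 data."""


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from CSV columns to (time, SmO2); names or 0-based indices."""

    time: str | int = "time_s"
    smo2: str | int = "smo2_pct"


@dataclass(frozen=True)
class ManifestRow:
    path: Path
    subject_id: str
    muscle: Muscle
    condition: Condition


@dataclass
class CohortManifest:
    """Ordered list of trial files with their metadata.

    Invariant: no duplicate (subject, muscle, condition) triple.
    """

    rows: list[ManifestRow]

    def __post_init__(self) -> None:
        triples = Counter(
            (r.subject_id, r.muscle, r.condition) for r in self.rows
        )
        dups = [t for t, c in triples.items() if c > 1]
        if dups:
            raise SignalIOError(
                f"duplicate (subject, muscle, condition) triples: {dups}"
            )

    def __len__(self) -> int:
        return len(self.rows)

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortManifest":
        path = Path(path)
        if not path.exists():
            raise SignalIOError(f"manifest not found: {path}")
        if path.suffix.lower() in {".yml", ".yaml"}:
            records = yaml.safe_load(path.read_text())
            if not isinstance(records, list):
                raise SignalIOError(f"YAML manifest must be a list: {path}")
            df = pd.DataFrame(records)
        else:
            df = pd.read_csv(path)
        required = {"path", "subject_id", "muscle", "condition"}
        missing = required - set(df.columns)
        if missing:
            raise SignalIOError(f"manifest {path} missing columns {missing}")
        rows = []
        for rec in df.itertuples(index=False):
            p = Path(rec.path)
            if not p.is_absolute():
                p = path.parent / p
            rows.append(
                ManifestRow(
                    path=p,
                    subject_id=str(rec.subject_id),
                    muscle=Muscle(rec.muscle),
                    condition=Condition(rec.condition),
                )
            )
        return cls(rows)


@dataclass
class Cohort:
    """Loaded traces with grouped accessors by muscle x condition."""

    traces: list[SmO2Trace] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.traces)

    def group(self, muscle: Muscle, condition: Condition) -> list[SmO2Trace]:
        return [
            t
            for t in self.traces
            if t.muscle is muscle and t.condition is condition
        ]

    def group_sizes(self) -> dict[tuple[Muscle, Condition], int]:
        sizes: dict[tuple[Muscle, Condition], int] = {}
        for m in Muscle:
            for c in Condition:
                sizes[(m, c)] = len(self.group(m, c))
        return sizes


def _read_column(df: pd.DataFrame, col: str | int, path: Path) -> np.ndarray:
    if isinstance(col, int):
        if col >= df.shape[1]:
            raise SignalIOError(f"{path}: no column at index {col}")
        series = df.iloc[:, col]
    else:
        if col not in df.columns:
            raise SignalIOError(
                f"{path}: missing column {col!r} (have {list(df.columns)})"
            )
        series = df[col]
    out = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
    if np.isnan(out).any():
        bad = int(np.flatnonzero(np.isnan(out))[0])
        raise SignalIOError(f"{path}: non-numeric cell in row {bad}")
    return out


def load_trial(
    path: str | Path,
    subject_id: str,
    muscle: Muscle | str,
    condition: Condition | str,
    columns: ColumnMap | None = None,
    nominal_dt: float | None = None,
    smoothed: bool = True,
    clip: bool = False,
) -> SmO2Trace:
    """Read one trial CSV and validate it into a trace.

    ``clip=True`` clamps out-of-range SmO2 values to [0, 100] instead of
    rejecting the file (default: reject).
    """
    path = Path(path)
    columns = columns or ColumnMap()
    if not path.exists():
        raise SignalIOError(f"trial file not found: {path}")
    try:
        df = pd.read_csv(path, header=None if isinstance(columns.time, int) else 0)
    except pd.errors.EmptyDataError:
        raise SignalIOError(f"{path}: no samples") from None
    if df.empty:
        raise SignalIOError(f"{path}: no samples")
    times = _read_column(df, columns.time, path)
    values = _read_column(df, columns.smo2, path)
    if clip:
        values = np.clip(values, 0.0, 100.0)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise SignalIOError(f"{path}: time column is not strictly increasing")
    if nominal_dt is None:
        nominal_dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    try:
        return SmO2Trace(
            subject_id=subject_id,
            muscle=Muscle(muscle),
            condition=Condition(condition),
            times=times,
            values=values,
            nominal_dt=nominal_dt,
            smoothed=smoothed,
        )
    except TraceValidationError as exc:
        raise SignalIOError(f"{path}: {exc}") from exc


def write_trial(trace: SmO2Trace, path: str | Path) -> Path:
    """Write a trace as canonical ``time_s,smo2_pct`` CSV."""
    trace.validate()
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times, "smo2_pct": trace.values})
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def load_cohort(
    manifest: CohortManifest | str | Path,
    columns: ColumnMap | None = None,
    strict: bool = True,
    **trial_kwargs,
) -> Cohort:
    """Load every trial listed in a manifest.

    In strict mode (default) any unreadable file aborts the whole load; in
    lenient mode failing files are logged and skipped.
    """
    if not isinstance(manifest, CohortManifest):
        manifest = CohortManifest.from_file(manifest)
    traces: list[SmO2Trace] = []
    failures: list[str] = []
    for row in manifest.rows:
        try:
            traces.append(
                load_trial(
                    row.path,
                    subject_id=row.subject_id,
                    muscle=row.muscle,
                    condition=row.condition,
                    columns=columns,
                    **trial_kwargs,
                )
            )
        except SignalIOError as exc:
            if strict:
                raise
            failures.append(str(exc))
            log.warning("skipping trial: %s", exc)
    if failures:
        log.warning("lenient cohort load skipped %d file(s)", len(failures))
    return Cohort(traces)


def write_manifest(rows: list[ManifestRow], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "path": [
                str(r.path.relative_to(path.parent))
                if r.path.is_relative_to(path.parent)
                else str(r.path)
                for r in rows
            ],
            "subject_id": [r.subject_id for r in rows],
            "muscle": [r.muscle.value for r in rows],
            "condition": [r.condition.value for r in rows],
        }
    )
    df.to_csv(path, index=False)
    return path
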