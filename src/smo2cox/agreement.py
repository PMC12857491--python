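"""Multi-rater agreement analytics for binary plateau annotations.

Covers Fleiss' kappa with the Landis-Koch interpretation bands, the
"at least 3 of 4 raters" consensus rule used to confirm a plateau from visual
assessment, and pairwise percent agreement between any two binary
determination methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import aggregate_raters
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

log = logging.getLogger(__name__)

#: Landis-Koch bands as (upper bound, label); intervals are right-closed so a
#: kappa of exactly 0.60 is "moderate" and 0.80 is "substantial".
KAPPA_BANDS: list[tuple[float, str]] = [
    (0.0, "poor"),  # kappa < 0
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
]


class AgreementError(ValueError):
    pass


@dataclass
class RatingMatrix:
    """Complete items x raters binary matrix of plateau yes/no ratings."""

    ratings: pd.DataFrame  # index: trial ids, columns: rater ids, values 0/1
    rater_class: str = "expert"  # "expert" | "non_expert"

    def __post_init__(self) -> None:
        df = self.ratings
        if df.shape[0] < 1:
            raise AgreementError("rating matrix needs at least 1 item")
        if df.shape[1] < 2:
            raise AgreementError("rating matrix needs at least 2 raters")
        if df.isna().any().any():
            raise AgreementError("rating matrix has missing cells")
        arr = df.to_numpy()
        if not np.isin(arr, [0, 1, True, False]).all():
            raise AgreementError("ratings must be binary (0/1)")
        self.ratings = df.astype(int)

    @property
    def n_items(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[1]

    @classmethod
    def from_csv(cls, path, rater_class: str = "expert") -> "RatingMatrix":
        """Read a ratings CSV: one row per trial, first column trial_id,
        remaining columns one per rater with yes/no or 1/0 values."""
        df = pd.read_csv(path, index_col=0)
        decode = {"yes": 1, "no": 0, "y": 1, "n": 0, "1": 1, "0": 0}
        df = df.apply(
            lambda col: col.map(lambda x: decode.get(str(x).lower(), x))
        ).astype(int)
        return cls(df, rater_class=rater_class)


@dataclass
class AgreementResult:
    """Fleiss' kappa with its interpretation band.

    ``kappa`` is None when chance agreement is exactly 1 (all ratings fall in
    a single category), where the chance-corrected statistic is
    mathematically indeterminate even though raw agreement is perfect.
    """

    kappa: float | None
    band: str
    n_items: int
    n_raters: int


def fleiss_kappa(m: RatingMatrix) -> AgreementResult:
    """Chance-corrected agreement among n raters on binary items.

    kappa = (P_bar - P_bar_e) / (1 - P_bar_e), where the per-item agreement is
    P_i = [sum_j n_ij (n_ij - 1)] / [n (n - 1)] over category counts n_ij.
    """
    counts, _ = aggregate_raters(m.ratings.to_numpy(), n_cat=2)
    p_cat = counts.sum(axis=0) / counts.sum()
    p_bar_e = float((p_cat**2).sum())
    if p_bar_e == 1.0:
        log.info(
            "all %d ratings fall in one category: raw agreement is perfect "
            "but Fleiss' kappa is undefined",
            m.n_items * m.n_raters,
        )
        return AgreementResult(None, "undefined", m.n_items, m.n_raters)
    kappa = float(_sm_fleiss_kappa(counts, method="fleiss"))
    return AgreementResult(kappa, kappa_band(kappa), m.n_items, m.n_raters)


def kappa_band(kappa: float | None) -> str:
    """Landis-Koch label for a kappa value (None -> "undefined")."""
    if kappa is None:
        return "undefined"
    if not -1.0 <= kappa <= 1.0:
        raise AgreementError(f"kappa {kappa} outside [-1, 1]")
    if kappa < 0:
        return "poor"
    for upper, label in KAPPA_BANDS[1:]:
        if kappa <= upper:
            return label
    return "almost perfect"  # unreachable; guards float edge cases


def consensus_vote(m: RatingMatrix, min_agree: int = 3) -> pd.Series:
    """Per-item consensus: positive iff at least ``min_agree`` raters said yes.

    With 4 raters and the default min_agree of 3, a 2-2 split is negative.
    """
    if min_agree > m.n_raters:
        raise AgreementError(
            f"min_agree={min_agree} exceeds the {m.n_raters} raters"
        )
    return (m.ratings.sum(axis=1) >= min_agree).rename("consensus")


def percent_agreement(a, b) -> float:
    """100 x (matching items) / (items) between two aligned binary vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise AgreementError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise AgreementError("empty input")
    return float(100.0 * np.mean(a == b))
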