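"""Critical-oxygenation (COx) plateau detection.

The COx plateau is defined as a stable SmO2 stretch of 30 s somewhere within
the last 45 s of a 3-min all-out test. With the test starting at second 0 the
search region is [135, 180]; candidate 30-s windows start at integer seconds
s in {135, ..., 150} and span [s, s + 30] inclusive (31 samples at 1 Hz).

Stability is judged by a threshold criterion in one of two modes:

* absolute — changes measured in arbitrary units (a.u.) of %SmO2,
  thresholds of +/-5 ("A5") and +/-10 ("A10") a.u.;
* relative — changes measured as percent of a reference value, thresholds of
  +/-5% ("R5") and +/-10% ("R10").

and one of two stability metrics:

* anchored (default) — every sample's change from the window's first value
  must stay within [-T, +T]; the reference for relative mode is that first
  value;
* range — the window's max - min must not exceed T.

Bounds are inclusive: a worst deviation of exactly T still counts as stable
(benefit-of-the-doubt convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocessing import extract_segment
from .trace import Segment, SmO2Trace

log = logging.getLogger(__name__)

DEFAULT_REGION = (135, 180)
DEFAULT_WINDOW_S = 30


class DetectionError(ValueError):
    pass


@dataclass(frozen=True)
class PlateauCriterion:
    """A parameterized plateau-detection rule.

    ``threshold`` is a positive magnitude: a.u. of %SmO2 in absolute mode,
    percent of the anchor value in relative mode.
    """

    mode: str  # "absolute" | "relative"
    threshold: float
    window_s: int = DEFAULT_WINDOW_S
    region: tuple[int, int] = DEFAULT_REGION
    stability_metric: str = "anchored"  # "anchored" | "range"

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "relative"):
            raise DetectionError(f"unknown mode {self.mode!r}")
        if self.stability_metric not in ("anchored", "range"):
            raise DetectionError(
                f"unknown stability metric {self.stability_metric!r}"
            )
        if self.threshold <= 0:
            raise DetectionError("threshold must be > 0")
        if self.window_s > self.region[1] - self.region[0]:
            raise DetectionError("window_s exceeds the search region length")

    @property
    def label(self) -> str:
        prefix = "A" if self.mode == "absolute" else "R"
        t = self.threshold
        return f"{prefix}{t:g}"


def default_criteria(
    stability_metric: str = "anchored",
    window_s: int = DEFAULT_WINDOW_S,
    region: tuple[int, int] = DEFAULT_REGION,
) -> dict[str, PlateauCriterion]:
    """The standard battery: A5, A10 (a.u.) and R5, R10 (percent)."""
    battery = {}
    for mode, thr in [
        ("absolute", 5.0),
        ("absolute", 10.0),
        ("relative", 5.0),
        ("relative", 10.0),
    ]:
        c = PlateauCriterion(
            mode=mode,
            threshold=thr,
            window_s=window_s,
            region=region,
            stability_metric=stability_metric,
        )
        battery[c.label] = c
    return battery


@dataclass
class PlateauResult:
    """Binary determination plus the winning window and observed deviation.

    ``max_deviation`` is the signed deviation of largest magnitude in the
    reported window: the earliest stable window when detected, otherwise the
    least-unstable candidate. Units follow the criterion mode (a.u. or
    percent of the anchor).
    """

    detected: bool
    window_start_s: int | None
    max_deviation: float
    criterion: PlateauCriterion = field(repr=False)


def _deviations(values: np.ndarray, criterion: PlateauCriterion) -> np.ndarray:
    """Per-sample signed deviations in the criterion's units."""
    v0 = values[0]
    if criterion.stability_metric == "anchored":
        dev = values - v0
    else:  # range: single deviation, the (positive) spread
        dev = np.array([values.max() - values.min()])
    if criterion.mode == "relative":
        if v0 == 0:
            raise DetectionError(
                "relative criterion undefined: window anchor value is 0"
            )
        dev = 100.0 * dev / v0
    return dev


def window_is_stable(
    segment: Segment | np.ndarray, criterion: PlateauCriterion
) -> tuple[bool, float]:
    """Judge one candidate window; return (stable, worst signed deviation)."""
    values = segment.values if isinstance(segment, Segment) else np.asarray(
        segment, dtype=float
    )
    if len(values) != criterion.window_s + 1:
        raise DetectionError(
            f"window of {criterion.window_s} s needs "
            f"{criterion.window_s + 1} samples, got {len(values)}"
        )
    dev = _deviations(values, criterion)
    worst = float(dev[np.argmax(np.abs(dev))])
    return abs(worst) <= criterion.threshold, worst


def detect_plateau(
    trace: SmO2Trace, criterion: PlateauCriterion
) -> PlateauResult:
    """Scan candidate windows in the search region; earliest stable wins.

    The trace must already be on the 1-Hz integer-second grid and cover the
    criterion's region. When no window is stable, the least-unstable window's
    deviation is reported with ``window_start_s = None``.
    """
    region_start, region_end = criterion.region
    segment = extract_segment(trace, region_start, region_end)
    if np.all(segment.values == 0.0) or np.all(segment.values == 100.0):
        log.warning(
            "trace %s: search region flat at the device floor/ceiling; "
            "classification is physiologically suspect",
            trace.subject_id,
        )
    best_unstable: tuple[float, int] | None = None
    for s in range(region_start, region_end - criterion.window_s + 1):
        window = segment.values[s - region_start : s - region_start + criterion.window_s + 1]
        stable, worst = window_is_stable(window, criterion)
        if stable:
            return PlateauResult(
                detected=True,
                window_start_s=s,
                max_deviation=worst,
                criterion=criterion,
            )
        if best_unstable is None or abs(worst) < abs(best_unstable[0]):
            best_unstable = (worst, s)
    assert best_unstable is not None
    return PlateauResult(
        detected=False,
        window_start_s=None,
        max_deviation=best_unstable[0],
        criterion=criterion,
    )


def classify_all_criteria(
    trace: SmO2Trace,
    criteria: dict[str, PlateauCriterion] | None = None,
) -> dict[str, PlateauResult]:
    """Run a battery of criteria on one trace; default is A5/A10/R5/R10."""
    criteria = criteria if criteria is not None else default_criteria()
    return {cid: detect_plateau(trace, c) for cid, c in criteria.items()}
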