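"""Core containers for muscle-oxygen-saturation (SmO2) time series.

A trace holds one trial of a wearable-NIRS oximeter signal (0-100 %, arbitrary
units) with times expressed in seconds relative to the start of the 3-min
all-out effort: the test spans [0, 180] and a full recorded sample typically
spans [-30, 210] (30 s of pre-test baseline and 30 s of recovery).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)

TEST_START_S = 0
TEST_END_S = 180


class Muscle(enum.Enum):
    VASTUS_LATERALIS = "vastus_lateralis"
    TRICEPS_BRACHII = "triceps_brachii"


class Condition(enum.Enum):
    NORMOXIA = "normoxia"
    HYPOXIA = "hypoxia"


class TraceValidationError(ValueError):
    """A signal violates the SmO2 trace invariants."""


@dataclass
class SmO2Trace:
    """One trial's time-stamped SmO2 signal plus acquisition metadata.

    Parameters
    ----------
    subject_id
        Opaque subject identifier.
    muscle, condition
        Measurement site and ambient-oxygen condition.
    times
        Sample times in seconds relative to test start, strictly increasing.
    values
        SmO2 in % arbitrary units, each within [0, 100].
    nominal_dt
        Nominal sampling interval in seconds (2 s for the Moxy default).
    smoothed
        True when the device's real-time 5-s moving average has already been
        applied (the Moxy firmware default).
    """

    subject_id: str
    muscle: Muscle
    condition: Condition
    times: np.ndarray
    values: np.ndarray
    nominal_dt: float = 2.0
    smoothed: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise TraceValidationError("times and values must be 1-D")
        if len(self.times) != len(self.values):
            raise TraceValidationError(
                f"length mismatch: {len(self.times)} times vs "
                f"{len(self.values)} values"
            )
        if len(self.times) == 0:
            raise TraceValidationError("no samples")
        if not np.all(np.isfinite(self.times)) or not np.all(
            np.isfinite(self.values)
        ):
            raise TraceValidationError("non-finite times or values")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise TraceValidationError("times must be strictly increasing")
        if self.nominal_dt <= 0:
            raise TraceValidationError("nominal_dt must be > 0")
        lo, hi = self.values.min(), self.values.max()
        if lo < 0.0 or hi > 100.0:
            raise TraceValidationError(
                f"SmO2 values must lie in [0, 100]; observed [{lo}, {hi}]"
            )
        # device floor/ceiling values are legal but suspect: a window clipped
        # flat at 0 or 100 can look spuriously stable
        if lo == 0.0 or hi == 100.0:
            log.warning(
                "trace %s contains values at the device floor/ceiling (0 or 100)",
                self.subject_id,
            )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def start_s(self) -> float:
        return float(self.times[0])

    @property
    def end_s(self) -> float:
        return float(self.times[-1])

    def covers(self, start_s: float, end_s: float) -> bool:
        """Whether the sampled range includes [start_s, end_s]."""
        return self.start_s <= start_s and self.end_s >= end_s

    def covers_test(self) -> bool:
        """A valid 3-min-test trace covers at least [0, 180] s."""
        return self.covers(TEST_START_S, TEST_END_S)

    def with_signal(
        self, times: np.ndarray, values: np.ndarray, **changes
    ) -> "SmO2Trace":
        """Copy of this trace with a new signal (metadata preserved)."""
        return replace(self, times=times, values=values, **changes)


@dataclass
class Segment:
    """A contiguous slice of a 1-Hz trace on the integer-second grid.

    Bounds are inclusive, so a segment spanning [a, b] carries b - a + 1
    samples: the 45-s end-of-test search region [135, 180] holds 46 values and
    each 30-s candidate window holds 31.
    """

    start_s: int
    end_s: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.end_s < self.start_s:
            raise ValueError("end_s must be >= start_s")
        expected = self.end_s - self.start_s + 1
        if len(self.values) != expected:
            raise ValueError(
                f"segment [{self.start_s}, {self.end_s}] needs {expected} "
                f"values, got {len(self.values)}"
            )
        if self.values.min() < 0.0 or self.values.max() > 100.0:
            raise ValueError("segment values must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.start_s, self.end_s + 1, dtype=float)
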