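"""Signal conditioning: 5-s moving average, 1-Hz resampling, window extraction.

The processing chain mirrors the acquisition convention of wearable Moxy
oximeters: the device samples every 2 s and applies a real-time (trailing)
5-s moving average; analysis then interpolates the record onto a 1-Hz
integer-second grid so that candidate plateau windows can be indexed by whole
seconds.
"""

from __future__ import annotations

import numpy as np

from .trace import Segment, SmO2Trace


class PreprocessingError(ValueError):
    pass


def moving_average(
    trace: SmO2Trace, width: float = 5.0, center: bool = False
) -> SmO2Trace:
    """Time-based moving average over all samples within ``width`` seconds.

    Default is trailing (causal): output at time t averages samples in
    (t - width, t] -- everything strictly within the preceding ``width``
    seconds plus the current sample -- matching a device that smooths in real
    time. Support shortens at the left edge. ``center=True`` instead averages
    [t - width/2, t + width/2] for sensitivity analyses.
    """
    if width <= 0:
        raise PreprocessingError("width must be > 0")
    if width < trace.nominal_dt:
        raise PreprocessingError(
            f"width {width} s is below the sampling interval "
            f"{trace.nominal_dt} s"
        )
    t, v = trace.times, trace.values
    if center:
        lo = np.searchsorted(t, t - width / 2, side="left")
        hi = np.searchsorted(t, t + width / 2, side="right")
    else:
        lo = np.searchsorted(t, t - width, side="right")
        hi = np.arange(1, len(t) + 1)
    csum = np.concatenate(([0.0], np.cumsum(v)))
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return trace.with_signal(t, out, smoothed=True)


def resample_to_1hz(trace: SmO2Trace, max_gap_s: float = 4.0) -> SmO2Trace:
    """Linearly interpolate onto the integer-second grid within the record.

    The grid spans [ceil(first time), floor(last time)]; values outside the
    sampled range are never fabricated by extrapolation. A gap between
    consecutive samples larger than ``max_gap_s`` aborts with the gap's
    location, since interpolating across a dropout would invent signal.
    """
    if len(trace) < 2:
        raise PreprocessingError("resampling needs at least 2 samples")
    t, v = trace.times, trace.values
    gaps = np.diff(t)
    if np.any(gaps > max_gap_s):
        i = int(np.argmax(gaps > max_gap_s))
        raise PreprocessingError(
            f"gap of {gaps[i]:.3g} s between t={t[i]:.3g} and "
            f"t={t[i + 1]:.3g} exceeds max_gap_s={max_gap_s}"
        )
    grid = np.arange(np.ceil(t[0]), np.floor(t[-1]) + 1)
    if len(grid) == 0:
        raise PreprocessingError("sampled range contains no integer second")
    out = np.interp(grid, t, v)
    return trace.with_signal(grid, out, nominal_dt=1.0)


def extract_segment(trace: SmO2Trace, start_s: int, end_s: int) -> Segment:
    """Inclusive integer-second slice of a 1-Hz trace.

    A 45-s region yields 46 samples; each 30-s window yields 31.
    """
    if trace.nominal_dt != 1.0:
        raise PreprocessingError("trace must be resampled to 1 Hz first")
    idx_start = np.searchsorted(trace.times, start_s)
    idx_end = np.searchsorted(trace.times, end_s)
    if (
        idx_start >= len(trace)
        or idx_end >= len(trace)
        or trace.times[idx_start] != start_s
        or trace.times[idx_end] != end_s
    ):
        raise PreprocessingError(
            f"region [{start_s}, {end_s}] not covered by trace "
            f"[{trace.start_s:.0f}, {trace.end_s:.0f}]"
        )
    return Segment(
        start_s=int(start_s),
        end_s=int(end_s),
        values=trace.values[idx_start : idx_end + 1],
    )


def standard_pipeline(
    trace: SmO2Trace,
    ma_width: float = 5.0,
    max_gap_s: float = 4.0,
    center: bool = False,
    force_smooth: bool = False,
) -> SmO2Trace:
    """Default conditioning: smooth (unless already device-smoothed), then 1 Hz.

    The double-smoothing guard skips the moving average when the trace is
    flagged as already smoothed by the device firmware; ``force_smooth``
    overrides it.
    """
    if force_smooth or not trace.smoothed:
        trace = moving_average(trace, width=ma_width, center=center)
    return resample_to_1hz(trace, max_gap_s=max_gap_s)
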