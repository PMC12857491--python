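import numpy as np
import pytest

from smo2cox import Condition, Muscle, SmO2Trace


def make_trace(times, values, subject="T01", **kw):
    kw.setdefault("muscle", Muscle.VASTUS_LATERALIS)
    kw.setdefault("condition", Condition.NORMOXIA)
    return SmO2Trace(
        subject_id=subject,
        times=np.asarray(times, dtype=float),
        values=np.asarray(values, dtype=float),
        **kw,
    )


def make_1hz_trace(values, start_s=0, **kw):
    """Trace already on the integer-second grid starting at start_s."""
    values = np.asarray(values, dtype=float)
    times = start_s + np.arange(len(values))
    kw.setdefault("nominal_dt", 1.0)
    return make_trace(times, values, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20260301)


@pytest.fixture
def random_region_trace(rng):
    """Factory for random 1-Hz traces covering the [135, 180] search region."""

    def factory(low=5.0, high=80.0, start=130, stop=185):
        n = stop - start + 1
        base = rng.uniform(low, high)
        walk = np.cumsum(rng.normal(0.0, 1.5, size=n))
        values = np.clip(base + walk - walk[0], 0.5, 100.0)
        return make_1hz_trace(values, start_s=start)

    return factory
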