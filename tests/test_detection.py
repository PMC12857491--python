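import numpy as np
import pytest

from smo2cox import (
    PlateauCriterion,
    classify_all_criteria,
    default_criteria,
    detect_plateau,
    window_is_stable,
)
from smo2cox.detection import DetectionError

from .conftest import make_1hz_trace


def oracle_window_stable(values, mode, threshold, metric):
    """Independent per-sample check of the stability definition."""
    v0 = values[0]
    if metric == "anchored":
        devs = [v - v0 for v in values]
    else:
        devs = [max(values) - min(values)]
    if mode == "relative":
        devs = [100.0 * d / v0 for d in devs]
    return all(-threshold <= d <= threshold for d in devs)


def oracle_detect(values_135_180, mode, threshold, metric="anchored"):
    """Exhaustive scan over every candidate start in {135..150}."""
    for s in range(0, 16):
        if oracle_window_stable(
            values_135_180[s : s + 31], mode, threshold, metric
        ):
            return True, 135 + s
    return False, None


A5 = PlateauCriterion(mode="absolute", threshold=5.0)
A10 = PlateauCriterion(mode="absolute", threshold=10.0)


class TestWindowIsStable:
    def test_constant_window_is_stable_with_zero_deviation(self):
        stable, dev = window_is_stable(np.full(31, 20.0), A5)
        assert stable and dev == 0.0

    def test_six_unit_rise_fails_a5_with_signed_deviation(self):
        stable, dev = window_is_stable(np.linspace(50, 56, 31), A5)
        assert not stable
        assert dev == pytest.approx(6.0)

    def test_deviation_exactly_at_threshold_is_stable(self):
        stable, dev = window_is_stable(np.linspace(20.0, 25.0, 31), A5)
        assert stable
        assert dev == pytest.approx(5.0)

    def test_relative_mode_with_zero_anchor_is_an_error(self):
        crit = PlateauCriterion(mode="relative", threshold=5.0)
        values = np.r_[0.0, np.full(30, 1.0)]
        with pytest.raises(DetectionError, match="anchor"):
            window_is_stable(values, crit)

    def test_wrong_window_length_rejected(self):
        with pytest.raises(DetectionError, match="31 samples"):
            window_is_stable(np.full(30, 20.0), A5)

    @pytest.mark.parametrize("mode", ["absolute", "relative"])
    @pytest.mark.parametrize("metric", ["anchored", "range"])
    def test_agrees_with_exhaustive_oracle_on_random_windows(
        self, rng, mode, metric
    ):
        crit = PlateauCriterion(
            mode=mode, threshold=5.0, stability_metric=metric
        )
        for _ in range(100):
            level = rng.uniform(5, 60)
            values = np.clip(
                level + np.cumsum(rng.normal(0, 0.4, size=31)), 0.5, 100
            )
            stable, dev = window_is_stable(values, crit)
            assert stable == oracle_window_stable(
                list(values), mode, 5.0, metric
            )
            # reported deviation never understates instability
            assert stable == (abs(dev) <= 5.0)


class TestDetectPlateau:
    def trace_covering_region(self, region_values):
        """1-Hz trace over [130, 185] whose [135, 180] slice is given."""
        values = np.r_[
            np.full(5, region_values[0]), region_values, np.full(5, region_values[-1])
        ]
        return make_1hz_trace(values, start_s=130)

    def test_constant_region_detects_earliest_window(self):
        tr = self.trace_covering_region(np.full(46, 30.0))
        res = detect_plateau(tr, A5)
        assert res.detected and res.window_start_s == 135

    def test_steady_decline_of_1au_per_s_is_never_stable(self):
        tr = self.trace_covering_region(60.0 - np.arange(46))
        res = detect_plateau(tr, A5)
        assert not res.detected
        assert res.window_start_s is None
        assert abs(res.max_deviation) == pytest.approx(30.0)

    def test_decline_then_flat_detects_at_the_elbow(self):
        # falls steeply (5.5 a.u./s) until t=150, then exactly constant:
        # every window starting before 150 still contains > 5 a.u. of fall
        region = np.r_[95.0 - 5.5 * np.arange(15), np.full(31, 12.5)]
        tr = self.trace_covering_region(region)
        res = detect_plateau(tr, A5)
        assert res.detected and res.window_start_s == 150
        truth = oracle_detect(list(region), "absolute", 5.0)
        assert (res.detected, res.window_start_s) == truth

    def test_agrees_with_brute_force_scan_on_random_traces(
        self, random_region_trace
    ):
        disagreements = 0
        for _ in range(100):
            tr = random_region_trace()
            region = tr.values[5:51]
            for crit in (A5, A10):
                res = detect_plateau(tr, crit)
                expect = oracle_detect(
                    list(region), "absolute", crit.threshold
                )
                assert (res.detected, res.window_start_s) == expect
                disagreements += res.detected != expect[0]
        assert disagreements == 0


class TestCriterionBattery:
    def test_default_battery_ids(self):
        assert list(default_criteria()) == ["A5", "A10", "R5", "R10"]

    def test_constant_trace_positive_under_all_criteria(self):
        tr = make_1hz_trace(np.full(56, 40.0), start_s=130)
        results = classify_all_criteria(tr)
        assert all(r.detected for r in results.values())

    def test_8au_drop_at_level_40_separates_absolute_from_relative(self):
        # anchored change of -8 a.u. in every window at ~40 a.u. (-20%)
        region = 40.0 - (8.0 / 30.0) * np.arange(46)
        values = np.r_[np.full(5, 40.0), region, np.full(5, region[-1])]
        tr = make_1hz_trace(values, start_s=130)
        res = classify_all_criteria(tr)
        assert not res["A5"].detected
        assert res["A10"].detected
        assert not res["R5"].detected
        assert not res["R10"].detected

    def test_small_absolute_change_on_low_plateau_fails_relative_5pct(self):
        # -1.5 a.u. anchored change at ~20 a.u. is -7.5%: A5/A10/R10 pass,
        # R5 fails -- a 5% threshold is under 1 a.u. at very low plateaus
        region = 20.0 - (1.5 / 30.0) * np.arange(46)
        values = np.r_[np.full(5, 20.0), region, np.full(5, region[-1])]
        tr = make_1hz_trace(values, start_s=130)
        res = classify_all_criteria(tr)
        assert res["A5"].detected and res["A10"].detected
        assert not res["R5"].detected
        assert res["R10"].detected


class TestDetectionProperties:
    def test_threshold_monotonicity_a5_subset_a10(self, random_region_trace):
        for _ in range(100):
            tr = random_region_trace()
            if detect_plateau(tr, A5).detected:
                assert detect_plateau(tr, A10).detected

    def test_range_stable_implies_anchored_stable_and_2t_converse(self, rng):
        anch = PlateauCriterion(mode="absolute", threshold=4.0)
        rnge = PlateauCriterion(
            mode="absolute", threshold=4.0, stability_metric="range"
        )
        anch2t = PlateauCriterion(mode="absolute", threshold=8.0,
                                  stability_metric="range")
        for _ in range(100):
            w = np.clip(
                30 + np.cumsum(rng.normal(0, 1.0, size=31)), 0.5, 100
            )
            if window_is_stable(w, rnge)[0]:
                assert window_is_stable(w, anch)[0]
            if window_is_stable(w, anch)[0]:
                assert window_is_stable(w, anch2t)[0]

    def test_offset_invariance_of_absolute_mode(self, random_region_trace):
        for _ in range(25):
            tr = random_region_trace(low=10, high=50)
            shifted = tr.with_signal(tr.times, tr.values + 10.0)
            assert (
                detect_plateau(tr, A5).detected
                == detect_plateau(shifted, A5).detected
            )

    def test_scale_invariance_of_relative_mode(self, random_region_trace):
        r5 = PlateauCriterion(mode="relative", threshold=5.0)
        for _ in range(25):
            tr = random_region_trace(low=20, high=80)
            scaled = tr.with_signal(tr.times, tr.values * 0.5)
            assert (
                detect_plateau(tr, r5).detected
                == detect_plateau(scaled, r5).detected
            )

    def test_detected_window_respects_result_invariants(
        self, random_region_trace
    ):
        for _ in range(50):
            tr = random_region_trace()
            res = detect_plateau(tr, A5)
            if res.detected:
                assert 135 <= res.window_start_s <= 150
                assert abs(res.max_deviation) <= 5.0


def test_criterion_validation():
    with pytest.raises(DetectionError):
        PlateauCriterion(mode="absolute", threshold=0.0)
    with pytest.raises(DetectionError):
        PlateauCriterion(mode="absolute", threshold=5.0, window_s=60)
    with pytest.raises(DetectionError):
        PlateauCriterion(mode="median", threshold=5.0)
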