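"""ROI time-courses, pixel slope maps and the nonpositive-slope deficit."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memriq.core import DynamicSeries, ImageVolume
from memriq.perfusion import (
    deficit_from_slopes,
    extract_roi_timecourse,
    fit_window_slope,
    pixel_slope_map,
    split_windows,
    TimeCourse,
)
from memriq.phantom import (
    UptakeKinetics,
    sector_width_for_fraction,
    simulate_memri_dynamics,
)


def make_series(data4d, times, windows=None, vox=(1.0, 1.0, 1.0)):
    frames = [ImageVolume(d, vox) for d in data4d]
    windows = windows or ["ischemia"] * len(frames)
    return DynamicSeries(frames, np.asarray(times, float), windows)


class TestSplitWindows:
    def test_partition_at_occlusion_time(self, small_spec):
        series, _ = simulate_memri_dynamics(small_spec)
        isch, rep = split_windows(series, 30.0)
        assert (isch.times_min <= 30.0).all()
        assert (rep.times_min > 30.0).all()
        restored = np.concatenate([isch.times_min, rep.times_min])
        np.testing.assert_array_equal(restored, series.times_min)

    def test_occlusion_outside_span_rejected(self, small_spec):
        series, _ = simulate_memri_dynamics(small_spec)
        with pytest.raises(ValueError):
            split_windows(series, 100.0)
        with pytest.raises(ValueError):
            split_windows(series, 0.5)


class TestRoiTimecourse:
    def test_matches_generator_closed_form(self, small_spec):
        kin = UptakeKinetics()
        series, truth = simulate_memri_dynamics(small_spec, kin)
        labels = truth.extras["labels"]
        tc = extract_roi_timecourse(series, labels, "septal")
        np.testing.assert_allclose(tc.si, kin.perfused_si(tc.t), rtol=1e-12)

    def test_single_voxel_roi_equals_trajectory(self, tiny_labels):
        data = np.random.default_rng(0).normal(size=(4, 4, 4, 1))
        series = make_series(data, [0, 1, 2, 3])
        lab = tiny_labels
        lab.sector[1, 2, 0] = 0  # shrink septal ROI to one voxel
        tc = extract_roi_timecourse(series, lab, "septal")
        np.testing.assert_allclose(tc.si, data[:, 1, 1, 0])

    def test_empty_roi_names_the_code(self, tiny_labels):
        series = make_series(np.zeros((2, 4, 4, 1)), [0, 1])
        tiny_labels.sector[tiny_labels.sector == 3] = 0
        with pytest.raises(ValueError, match="anterior"):
            extract_roi_timecourse(series, tiny_labels, "anterior")


class TestWindowSlope:
    def test_exact_line_recovered_with_significant_p(self):
        t = np.array([0.0, 6.0, 12.0, 18.0])
        tc = TimeCourse(t, 100.0 + 2.0 * t, 1, ["ischemia"] * 4)
        slope, intercept, p = fit_window_slope(tc, "ischemia")
        assert slope == pytest.approx(2.0, abs=1e-12)
        assert intercept == pytest.approx(100.0, abs=1e-9)
        assert p == 0.0

    def test_constant_signal_nonsignificant(self):
        tc = TimeCourse([0, 6, 12], [50.0, 50.0, 50.0], 1, ["ischemia"] * 3)
        slope, _, p = fit_window_slope(tc, "ischemia")
        assert slope == 0.0
        assert p == 1.0

    def test_matches_hand_computed_ols(self):
        t = np.array([0.0, 6.0, 12.0])
        si = np.array([10.0, 11.0, 13.0])
        tc = TimeCourse(t, si, 1, ["ischemia"] * 3)
        slope, intercept, _ = fit_window_slope(tc, "ischemia")
        expected_slope = ((t - t.mean()) * (si - si.mean())).sum() / ((t - t.mean()) ** 2).sum()
        assert slope == pytest.approx(expected_slope, rel=1e-12)
        assert intercept == pytest.approx(si.mean() - expected_slope * t.mean(), rel=1e-12)

    def test_too_few_frames_rejected(self):
        tc = TimeCourse([0, 6, 12], [1.0, 2.0, 3.0], 1, ["ischemia", "ischemia", "reperfusion"])
        with pytest.raises(ValueError):
            fit_window_slope(tc, "reperfusion")


class TestPixelSlopeMap:
    def test_identical_frames_give_zero_slope(self, tiny_labels):
        series = make_series(np.ones((3, 4, 4, 1)), [0, 10, 20])
        smap = pixel_slope_map(series, tiny_labels)
        myo = tiny_labels.myocardium_mask()
        assert (smap.slope[myo] == 0).all()
        assert np.isnan(smap.slope[~myo]).all()

    def test_endpoint_matches_generator_closed_form(self, small_spec):
        kin = UptakeKinetics()
        series, truth = simulate_memri_dynamics(small_spec, kin)
        labels = truth.extras["labels"]
        isch, _ = split_windows(series, kin.t_occlusion)
        smap = pixel_slope_map(isch, labels, mode="endpoint")
        t0, t1 = isch.times_min[0], isch.times_min[-1]
        expected = (kin.perfused_si(t1) - kin.perfused_si(t0)) / (t1 - t0)
        perfused = labels.myocardium_mask() & ~truth.ischemic_mask
        np.testing.assert_allclose(smap.slope[perfused], expected, rtol=1e-12)

    def test_modes_agree_on_linear_trajectories(self, tiny_labels):
        t = np.array([0.0, 5.0, 12.0, 20.0])
        base = np.random.default_rng(1).normal(size=(4, 4, 1))
        rate = np.random.default_rng(2).normal(size=(4, 4, 1))
        data = np.stack([base + rate * ti for ti in t])
        series = make_series(data, t)
        a = pixel_slope_map(series, tiny_labels, mode="endpoint")
        b = pixel_slope_map(series, tiny_labels, mode="ols")
        myo = tiny_labels.myocardium_mask()
        np.testing.assert_allclose(a.slope[myo], b.slope[myo], rtol=1e-10)

    def test_ols_matches_bruteforce_per_voxel(self):
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(0, 30, size=5))
        data = rng.normal(size=(5, 10, 10, 2))
        series = make_series(data, t)
        from memriq.core import LabelMap

        labels = LabelMap(np.full((10, 10, 2), 2, dtype=np.int16), (1, 1, 1))
        smap = pixel_slope_map(series, labels, mode="ols")
        brute = np.empty((10, 10, 2))
        for i in range(10):
            for j in range(10):
                for k in range(2):
                    brute[i, j, k] = np.polyfit(t, data[:, i, j, k], 1)[0]
        np.testing.assert_allclose(smap.slope, brute, atol=1e-10)


class TestDeficit:
    def test_strictly_positive_slopes_give_zero(self, tiny_labels):
        t = [0.0, 10.0, 20.0]
        data = np.stack([np.full((4, 4, 1), 1.0 + ti) for ti in t])
        series = make_series(data, t)
        res = deficit_from_slopes(pixel_slope_map(series, tiny_labels), tiny_labels)
        assert res.deficit_pct_lv == 0.0

    def test_zero_slope_counts_as_deficit(self, tiny_labels):
        series = make_series(np.ones((3, 4, 4, 1)), [0, 10, 20])
        res = deficit_from_slopes(pixel_slope_map(series, tiny_labels), tiny_labels)
        assert res.deficit_pct_lv == 100.0

    @pytest.mark.parametrize("target_pct", [10.0, 20.0, 30.0, 40.0])
    def test_noise_free_recovery_equals_truth(self, small_spec, target_pct):
        spec = replace(small_spec, ischemic_sector_deg=sector_width_for_fraction(target_pct))
        series, truth = simulate_memri_dynamics(spec)
        labels = truth.extras["labels"]
        isch, _ = split_windows(series, 30.0)
        res = deficit_from_slopes(pixel_slope_map(isch, labels), labels)
        assert res.deficit_pct_lv == truth.deficit_fraction_true

    @given(c=st.floats(min_value=0.001, max_value=10.0))
    @settings(max_examples=20, deadline=None)
    def test_adding_positive_trend_never_increases_deficit(self, c):
        rng = np.random.default_rng(3)
        t = np.array([0.0, 10.0, 20.0, 30.0])
        data = rng.normal(size=(4, 6, 6, 1))
        from memriq.core import LabelMap

        labels = LabelMap(np.full((6, 6, 1), 2, dtype=np.int16), (1, 1, 1))
        base = deficit_from_slopes(
            pixel_slope_map(make_series(data, t), labels), labels
        ).deficit_pct_lv
        trended = data + c * t[:, None, None, None]
        res = deficit_from_slopes(
            pixel_slope_map(make_series(trended, t), labels), labels
        ).deficit_pct_lv
        assert res <= base
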