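"""Geometry, kinetics and determinism of the synthetic LV phantom."""

from dataclasses import replace

import numpy as np
import pytest

from memriq.core import SECTOR_NONE
from memriq.phantom import (
    GeometryError,
    PhantomSpec,
    UptakeKinetics,
    bias_field,
    ischemic_mask,
    make_lv_labelmap,
    sector_width_for_fraction,
    simulate_cine,
    simulate_lge_volume,
    simulate_memri_dynamics,
    simulate_vfa_stack,
    make_t1_truth,
)
from memriq.t1 import spgr_signal


class TestLabelmapGeometry:
    def test_cavity_volume_matches_analytic_cylinder(self, full_spec):
        # pi * 1.5^2 * 8 mm^3 for the default ED endocardial radius
        labels = make_lv_labelmap(full_spec, "ED")
        vol = labels.cavity_mask().sum() * labels.voxel_volume_ul
        assert vol == pytest.approx(np.pi * 1.5**2 * 8.0, rel=0.03)

    def test_zero_endo_radius_gives_solid_disc(self, small_spec):
        spec = replace(small_spec, r_endo_ed=0.0)
        labels = make_lv_labelmap(spec, "ED")
        assert not labels.cavity_mask().any()
        assert labels.myocardium_mask().any()

    def test_sectors_partition_myocardium(self, small_spec):
        labels = make_lv_labelmap(small_spec, "ED")
        myo = labels.myocardium_mask()
        assert (labels.sector[myo] != SECTOR_NONE).all()
        assert (labels.sector[~myo] == SECTOR_NONE).all()
        counts = [labels.sector_mask(s).sum() for s in (1, 2, 3, 4)]
        assert sum(counts) == myo.sum()

    def test_oversized_annulus_rejected(self, small_spec):
        spec = replace(small_spec, r_epi_ed=50.0)
        with pytest.raises(GeometryError):
            make_lv_labelmap(spec, "ED")

    def test_es_radii_used_for_es_phase(self, small_spec):
        ed = make_lv_labelmap(small_spec, "ED")
        es = make_lv_labelmap(small_spec, "ES")
        assert es.cavity_mask().sum() < ed.cavity_mask().sum()


class TestMemriDynamics:
    def test_perfused_voxel_matches_closed_form(self, small_spec):
        kin = UptakeKinetics(s0=100.0, u_max=1.0, tau_up=15.0, d_rate=0.0)
        series, truth = simulate_memri_dynamics(small_spec, kin)
        labels = truth.extras["labels"]
        perfused = labels.myocardium_mask() & ~truth.ischemic_mask
        vox = np.argwhere(perfused)[0]
        for frame, t in zip(series.frames, series.times_min):
            expected = 100.0 * (1.0 + 1.0 * (1.0 - np.exp(-t / 15.0)))
            assert frame.data[tuple(vox)] == pytest.approx(expected, rel=1e-12)

    def test_ischemic_flat_when_decline_zero(self, small_spec):
        kin = UptakeKinetics(d_rate=0.0)
        series, truth = simulate_memri_dynamics(small_spec, kin)
        stack = np.stack(
            [f.data[truth.ischemic_mask] for f, t in zip(series.frames, series.times_min)
             if t <= kin.t_occlusion]
        )
        assert np.ptp(stack, axis=0).max() == 0.0

    def test_seed_determinism(self, small_spec):
        spec = replace(small_spec, noise_sigma=3.0, seed=42)
        a, _ = simulate_memri_dynamics(spec)
        b, _ = simulate_memri_dynamics(spec)
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa.data, fb.data)

    def test_truth_fraction_consistent_with_mask(self, small_spec):
        _, truth = simulate_memri_dynamics(small_spec)
        labels = truth.extras["labels"]
        recomputed = 100.0 * truth.ischemic_mask.sum() / labels.myocardium_mask().sum()
        assert truth.deficit_fraction_true == recomputed

    def test_perfused_uptake_monotone(self, small_spec):
        series, truth = simulate_memri_dynamics(small_spec, UptakeKinetics(u_max=1.5))
        labels = truth.extras["labels"]
        perfused = labels.myocardium_mask() & ~truth.ischemic_mask
        tc = np.stack([f.data[perfused] for f in series.frames])
        assert (np.diff(tc, axis=0) >= 0).all()

    def test_timestamps_are_interval_midpoints(self):
        kin = UptakeKinetics(t_total=66.0, n_frames=11)
        np.testing.assert_allclose(kin.timestamps(), 3.0 + 6.0 * np.arange(11))

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            UptakeKinetics(n_frames=1)

    def test_rigid_shift_applied_after_occlusion_only(self, small_spec):
        spec = replace(small_spec, shift_mm=(0.5, 0.0))
        base, _ = simulate_memri_dynamics(replace(small_spec, shift_mm=None))
        shifted, _ = simulate_memri_dynamics(spec)
        kin = UptakeKinetics()
        for fb, fs, t in zip(base.frames, shifted.frames, base.times_min):
            same = np.array_equal(fb.data, fs.data)
            assert same == (t <= kin.t_occlusion)


class TestVfaStack:
    def test_noise_free_equals_closed_form(self, small_spec):
        labels = make_lv_labelmap(small_spec, "ED")
        t1v, m0v = make_t1_truth(labels, t1_myo_ms=1490.0, m0=1000.0)
        vols = simulate_vfa_stack(small_spec, t1v, m0v, [2, 5, 8, 11, 14], 11.1)
        myo = labels.myocardium_mask()
        for alpha, vol in zip([2, 5, 8, 11, 14], vols):
            expected = spgr_signal(alpha, 1000.0, 1490.0, 11.1)
            np.testing.assert_allclose(vol.data[myo], expected, rtol=1e-12)

    def test_invalid_flip_angle_rejected(self, small_spec):
        labels = make_lv_labelmap(small_spec, "ED")
        t1v, m0v = make_t1_truth(labels)
        with pytest.raises(ValueError):
            simulate_vfa_stack(small_spec, t1v, m0v, [0.0, 5.0], 11.1)

    def test_nonpositive_t1_in_myocardium_rejected(self, small_spec):
        labels = make_lv_labelmap(small_spec, "ED")
        t1v, m0v = make_t1_truth(labels)
        t1v[labels.myocardium_mask()] = 0.0
        with pytest.raises(ValueError):
            simulate_vfa_stack(small_spec, t1v, m0v, [2.0, 5.0], 11.1)


class TestLgePhantom:
    def test_designed_fraction_recorded_to_voxel_quantum(self, small_spec):
        sector = sector_width_for_fraction(34.0)
        _, truth = simulate_lge_volume(small_spec, sector, 2.0)
        labels = truth.extras["labels"]
        quantum = 100.0 / labels.myocardium_mask().sum()
        assert truth.enhanced_fraction_true == pytest.approx(34.0, abs=100 * quantum)

    def test_lateral_enhancement_avoids_septum(self, small_spec):
        _, truth = simulate_lge_volume(small_spec, (-40.0, 40.0), 2.0)
        labels = truth.extras["labels"]
        assert not (truth.ischemic_mask & labels.sector_mask("septal")).any()

    def test_empty_sector_valid_with_zero_fraction(self, small_spec):
        vol, truth = simulate_lge_volume(small_spec, None, 2.0)
        assert truth.enhanced_fraction_true == 0.0
        assert np.isfinite(vol.data).all()

    def test_factor_at_most_one_rejected(self, small_spec):
        with pytest.raises(ValueError):
            simulate_lge_volume(small_spec, (-30, 30), 1.0)


class TestCine:
    def test_two_frames_are_ed_and_es(self, small_spec):
        maps, _ = simulate_cine(small_spec, 2)
        ed = make_lv_labelmap(small_spec, "ED")
        es = make_lv_labelmap(small_spec, "ES")
        np.testing.assert_array_equal(maps[0].tissue, ed.tissue)
        np.testing.assert_array_equal(maps[1].tissue, es.tissue)

    def test_ed_frame_has_maximal_cavity(self, small_spec):
        maps, truth = simulate_cine(small_spec, 20)
        counts = [m.cavity_mask().sum() for m in maps]
        assert counts[0] == max(counts)
        assert np.argmax(truth.cavity_volume_true_ul) == 0

    def test_impaired_sector_frozen_at_ed(self, small_spec):
        maps, _ = simulate_cine(small_spec, 20, impaired_sector_deg=(-45.0, 45.0))
        ed = maps[0]
        es_frame = maps[10]
        lat_ed = ed.sector_mask("lateral")
        lat_es = es_frame.sector_mask("lateral")
        assert lat_ed.sum() == lat_es.sum()  # lateral wall does not move
        assert es_frame.sector_mask("septal").sum() != ed.sector_mask("septal").sum()


def test_bias_field_unit_mean_and_determinism(small_spec):
    spec = replace(small_spec, bias_amplitude=0.3)
    f = bias_field(spec)
    assert f.mean() == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_array_equal(f, bias_field(spec))
    assert np.ptp(f) > 0.1


def test_rician_noise_is_nonnegative(small_spec):
    spec = replace(small_spec, noise_sigma=5.0, noise_model="rician", seed=7)
    series, _ = simulate_memri_dynamics(spec)
    assert (series.frames[0].data >= 0).all()
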