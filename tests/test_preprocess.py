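import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ke4dflow as k
from ke4dflow.errors import DegenerateDataError


def _zero_field(grid=(12, 12, 12), n_phases=6, spacing=(2.0, 2.0, 2.0)):
    meta = k.FlowMetadata(subject_id="z", voxel_spacing=spacing,
                          n_phases_acquired=n_phases)
    values = np.zeros((n_phases,) + grid + (3,))
    return k.VelocityField4D(values, k.uniform_phase_times(n_phases, 1000.0),
                             meta)


def _series_field(series, venc=100.0):
    """Single-voxel field whose x-component follows ``series`` over time."""
    n = len(series)
    vals = np.zeros((n, 1, 1, 1, 3))
    vals[:, 0, 0, 0, 0] = series
    meta = k.FlowMetadata(subject_id="s", venc=venc, n_phases_acquired=n)
    return k.VelocityField4D(vals, k.uniform_phase_times(n, 1000.0), meta)


class TestStaticTissueDetection:
    def test_zero_background_is_included(self, uniform_phantom):
        fld, masks, _ = uniform_phantom
        static = k.detect_static_tissue(fld)
        background = masks.labels[0] == 0
        assert np.all(static.member[background])

    def test_moving_roi_is_excluded(self, uniform_phantom):
        fld, masks, _ = uniform_phantom
        static = k.detect_static_tissue(fld, mean_threshold=5.0)
        roi = masks.labels[0] == k.LABEL_CODES["ventricle"]
        assert not np.any(static.member[roi])

    def test_zero_sd_threshold_on_noisy_field_errors(self):
        fld = _zero_field()
        noisy = k.inject_noise(fld, 1.0, seed=0)
        with pytest.raises(DegenerateDataError, match="relax"):
            k.detect_static_tissue(noisy, sd_threshold=0.0)


class TestEddyCorrection:
    def test_injected_plane_recovered_exactly(self, eddy_plane):
        fld = _zero_field()
        corrupted = k.inject_eddy_offset(fld, eddy_plane)
        static = k.detect_static_tissue(corrupted)
        fixed, fit = k.correct_eddy_currents(corrupted, static)
        scale = np.max(np.abs(eddy_plane))
        assert np.max(np.abs(fit.coefficients - eddy_plane)) / scale <= 1e-8
        # post-correction static-tissue time-averaged mean ~ 0
        resid = fixed.values.mean(axis=0)[static.member]
        assert np.max(np.abs(resid)) <= 1e-9

    def test_zero_plane_leaves_field_unchanged(self):
        fld = _zero_field()
        static = k.detect_static_tissue(fld)
        fixed, fit = k.correct_eddy_currents(fld, static)
        np.testing.assert_allclose(fixed.values, fld.values, atol=1e-12)
        assert np.max(np.abs(fit.coefficients)) <= 1e-12

    def test_coefficient_error_shrinks_with_static_count(self, eddy_plane):
        # Monte-Carlo over seeds: lstsq error ~ sigma/sqrt(N)
        errs = []
        for grid in ((8, 8, 8), (20, 20, 20)):
            per_seed = []
            for seed in range(8):
                fld = _zero_field(grid=grid)
                fld = k.inject_eddy_offset(fld, eddy_plane)
                fld = k.inject_noise(fld, 1.0, seed=seed)
                static = k.detect_static_tissue(fld)
                _, fit = k.correct_eddy_currents(fld, static)
                per_seed.append(np.abs(fit.coefficients[:, 0] - eddy_plane[:, 0]).mean())
            errs.append(np.mean(per_seed))
        assert errs[1] < errs[0]

    def test_coplanar_static_set_is_rank_deficient(self):
        fld = _zero_field()
        member = np.zeros(fld.grid_shape, dtype=bool)
        member[:, :, 3] = True  # a single z-plane: z term unidentifiable
        static = k.preprocess.StaticTissueMask(member, 1.0, 1.0)
        with pytest.raises(DegenerateDataError, match="rank"):
            k.correct_eddy_currents(fld, static)

    def test_correction_is_linear_in_injected_plane(self, eddy_plane):
        fld, _, _ = k.make_ventricle_phantom("systolic_dominant",
                                             n_phases=12, seed=2)
        static = k.detect_static_tissue(fld)
        _, fit_base = k.correct_eddy_currents(fld, static)
        shifted = k.inject_eddy_offset(fld, eddy_plane)
        _, fit_shift = k.correct_eddy_currents(shifted, static)
        np.testing.assert_allclose(fit_shift.coefficients,
                                   fit_base.coefficients + eddy_plane,
                                   atol=1e-9)


def _brute_force_unwrap(series, venc):
    """Minimize total variation over all 2*venc shift assignments."""
    best, best_tv = None, np.inf
    for ks in itertools.product((-2, -1, 0, 1, 2), repeat=len(series) - 1):
        cand = [series[0]]
        for step, kk in zip(np.diff(series), ks):
            cand.append(cand[-1] + step + 2 * venc * kk)
        tv = np.sum(np.abs(np.diff(cand)))
        if tv < best_tv:
            best_tv, best = tv, cand
    return np.array(best)


class TestUnwrapping:
    def test_three_sample_example_and_oracle(self):
        fld = _series_field([80.0, -80.0, 80.0])
        out, report = k.unwrap_velocity(fld)
        got = out.values[:, 0, 0, 0, 0]
        np.testing.assert_allclose(got, [80.0, 120.0, 80.0])
        oracle = _brute_force_unwrap([80.0, -80.0, 80.0], 100.0)
        np.testing.assert_allclose(got, oracle)
        assert report.n_corrected == 1

    def test_clean_series_untouched(self):
        fld = _series_field([10.0, 50.0, -40.0, 0.0])
        out, report = k.unwrap_velocity(fld)
        np.testing.assert_array_equal(out.values, fld.values)
        assert report.n_corrected == 0

    def test_recovers_injected_wraps_below_1p8_venc(self):
        fld, _, truth = k.make_ventricle_phantom(
            "systolic_dominant", n_phases=20, seed=3,
            peak_sys_mj=30.0, peak_dia_mj=18.0)
        assert np.abs(fld.values).max() <= 1.8 * fld.metadata.venc
        wrapped = k.inject_aliasing(fld, truth)
        assert truth.wrap_sites
        unwrapped, _ = k.unwrap_velocity(wrapped)
        # exact up to the one-ULP round trip of subtracting/re-adding 2*venc
        np.testing.assert_allclose(unwrapped.values, fld.values, atol=1e-9,
                                   rtol=0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-250, 250), min_size=2, max_size=8))
    def test_only_changes_by_multiples_of_two_venc(self, series):
        venc = 100.0
        fld = _series_field(series, venc=venc)
        out, _ = k.unwrap_velocity(fld)
        delta = (out.values - fld.values)[:, 0, 0, 0, 0]
        k_mult = delta / (2 * venc)
        np.testing.assert_allclose(k_mult, np.round(k_mult), atol=1e-9)


class TestPhaseReconstruction:
    def test_identity_when_aligned(self, uniform_phantom):
        fld, _, _ = uniform_phantom
        out = k.reconstruct_phases(fld, fld.n_phases)
        np.testing.assert_array_equal(out.values, fld.values)

    def test_constant_field_stays_constant(self):
        fld = _series_field([7.0] * 10)
        out = k.reconstruct_phases(fld, 23)
        np.testing.assert_allclose(out.values[:, 0, 0, 0, 0], 7.0)
        assert out.metadata.n_phases_reconstructed == 23

    def test_sinusoid_error_within_linear_interp_bound(self):
        n_in, n_out, amp = 20, 40, 60.0
        t = k.uniform_phase_times(n_in, 1000.0)
        series = amp * np.sin(2 * np.pi * t / 1000.0)
        fld = _series_field(series)
        out = k.reconstruct_phases(fld, n_out)
        analytic = amp * np.sin(2 * np.pi * out.phase_times / 1000.0)
        bound = (2 * np.pi / n_in) ** 2 / 8 * amp
        err = np.max(np.abs(out.values[:, 0, 0, 0, 0] - analytic))
        assert err <= bound * 1.01

    def test_cycle_mean_preserved_for_band_limited_input(self):
        t = k.uniform_phase_times(16, 1000.0)
        series = 30.0 + 20.0 * np.cos(2 * np.pi * t / 1000.0)
        fld = _series_field(series)
        out = k.reconstruct_phases(fld, 40)
        assert out.values[:, 0, 0, 0, 0].mean() == pytest.approx(30.0, rel=0.01)


class TestFullChain:
    def test_clean_field_passes_through_unchanged(self, uniform_phantom):
        fld, _, _ = uniform_phantom
        out, report = k.preprocess_field(fld, n_phases_out=fld.n_phases)
        scale = np.abs(fld.values).max()
        assert np.max(np.abs(out.values - fld.values)) / scale <= 1e-9
        assert report.n_wraps_corrected == 0

    def test_default_phase_count_is_forty(self, uniform_phantom):
        fld, _, _ = uniform_phantom
        out, _ = k.preprocess_field(fld)
        assert out.n_phases == 40
        assert out.metadata.n_phases_reconstructed == 40

    def test_mask_resampling_keeps_aligned_samples(self, ventricle_phantoms):
        fld, masks, _ = ventricle_phantoms["systolic_dominant"]
        out = k.resample_mask_series(masks, fld.phase_times,
                                     fld.metadata.rr_interval, 2 * fld.n_phases)
        np.testing.assert_array_equal(out.labels[::2], masks.labels)
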