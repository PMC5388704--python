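import math

import numpy as np
import pytest
from scipy import integrate

import ke4dflow as k
from ke4dflow.errors import FlowError, GeometryError


class TestUniformPhantom:
    def test_zero_speed_gives_zero_ke(self):
        _, _, truth = k.make_uniform_phantom(0.0, n_phases=4)
        assert np.all(truth.true_ke_curve == 0.0)

    def test_closed_form_hand_calculation(self, uniform_phantom):
        # 1000 voxels x 8 mm^3 -> 8 cm^3 of blood; mass 8.4 g;
        # KE = 0.5 * 0.0084 kg * (1 m/s)^2 = 4.2 mJ
        fld, masks, truth = uniform_phantom
        assert truth.true_ke_curve[0] == pytest.approx(4.2, rel=1e-12)
        curve = k.roi_ke_curve(fld, masks, "ventricle")
        np.testing.assert_allclose(curve.ke_per_phase, truth.true_ke_curve,
                                   rtol=1e-12)

    def test_doubling_speed_quadruples_ke(self):
        _, _, t1 = k.make_uniform_phantom(50.0, n_phases=4)
        _, _, t2 = k.make_uniform_phantom(100.0, n_phases=4)
        np.testing.assert_allclose(t2.true_ke_curve, 4.0 * t1.true_ke_curve,
                                   rtol=1e-12)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(FlowError, match="unit"):
            k.make_uniform_phantom(100.0, direction=(1.0, 1.0, 0.0))


class TestPoiseuilleVessel:
    def test_zero_vmax_gives_zero_ke(self):
        _, _, truth = k.make_poiseuille_vessel(10.0, 50.0, 0.0)
        assert np.all(truth.true_ke_curve == 0.0)

    def test_continuum_value_against_quadrature_oracle(self):
        # KE = 1/2 rho L \int v(r)^2 dA with v(r) = vmax (1 - r^2/R^2)
        R, L, vmax, rho = 10.0, 50.0, 100.0, 1.05
        integral, _ = integrate.quad(
            lambda r: (vmax * (1 - r**2 / R**2)) ** 2 * 2 * math.pi * r, 0, R)
        oracle_mj = 0.5 * rho * integral * L * 1e-7
        _, _, truth = k.make_poiseuille_vessel(R, L, vmax)
        assert truth.continuum_ke_mj == pytest.approx(oracle_mj, rel=1e-10)
        assert truth.continuum_ke_mj == pytest.approx(2.749, abs=5e-4)

    def test_discretization_error_small_and_shrinking(self):
        errs = []
        for h in (2.0, 1.0, 0.5):
            _, _, truth = k.make_poiseuille_vessel(
                10.0, 50.0, 100.0, spacing=(h, h, h), n_phases=2)
            errs.append(abs(truth.true_ke_curve[0] - truth.continuum_ke_mj)
                        / truth.continuum_ke_mj)
        assert errs[1] <= 0.03  # within 3% at 1 mm
        assert errs[0] >= errs[1] >= errs[2]

    def test_unresolvable_radius_rejected(self):
        with pytest.raises(GeometryError, match="resolvable"):
            k.make_poiseuille_vessel(3.0, 50.0, 100.0, spacing=(2.0, 2.0, 2.0))

    def test_cylinder_exceeding_grid_rejected(self):
        with pytest.raises(GeometryError, match="exceeds"):
            k.make_poiseuille_vessel(10.0, 50.0, 100.0, grid=(12, 12, 60))


class TestVentriclePhantom:
    @pytest.mark.parametrize("pattern,cmp", [
        ("diastolic_dominant", lambda r: r < 1),
        ("systolic_dominant", lambda r: r > 1),
    ])
    def test_truth_peak_ratio_matches_pattern(self, ventricle_phantoms,
                                              pattern, cmp):
        _, _, truth = ventricle_phantoms[pattern]
        ratio = truth.extras["peak_sys_mj"] / truth.extras["peak_dia_mj"]
        assert cmp(ratio)

    def test_measured_ke_matches_template(self, ventricle_phantoms):
        fld, masks, truth = ventricle_phantoms["systolic_dominant"]
        curve = k.roi_ke_curve(fld, masks, "ventricle")
        err = np.max(np.abs(curve.ke_per_phase - truth.true_ke_curve))
        assert err <= 0.02 * truth.true_ke_curve.max()

    def test_same_seed_is_bit_identical(self):
        a = k.make_ventricle_phantom("plateau", n_phases=12, seed=5,
                                     noise_sigma=1.0)
        b = k.make_ventricle_phantom("plateau", n_phases=12, seed=5,
                                     noise_sigma=1.0)
        np.testing.assert_array_equal(a[0].values, b[0].values)

    def test_unknown_pattern_rejected(self):
        with pytest.raises(FlowError, match="pattern"):
            k.make_ventricle_phantom("sideways", n_phases=12, seed=0)

    def test_truth_curves_nonnegative(self, ventricle_phantoms):
        for _, _, truth in ventricle_phantoms.values():
            assert np.all(truth.true_ke_curve >= 0)
            assert np.all(truth.true_volume_curve > 0)


class TestCorruptionInjectors:
    def test_zero_plane_is_identity(self, uniform_phantom):
        fld, _, _ = uniform_phantom
        out = k.inject_eddy_offset(fld, np.zeros((3, 4)))
        np.testing.assert_array_equal(out.values, fld.values)

    def test_offset_only_plane_shifts_component(self, uniform_phantom):
        fld, _, _ = uniform_phantom
        plane = np.zeros((3, 4))
        plane[0, 0] = 2.5
        out = k.inject_eddy_offset(fld, plane)
        np.testing.assert_allclose(out.values[..., 0] - fld.values[..., 0], 2.5)
        np.testing.assert_array_equal(out.values[..., 1:], fld.values[..., 1:])

    @pytest.mark.parametrize("v,expected", [
        (120.0, -80.0),   # 120 - 200
        (80.0, 80.0),     # within range
        (-130.0, 70.0),   # -130 + 200
    ])
    def test_wrap_arithmetic(self, v, expected):
        assert k.phantom.wrap_to_venc(np.array([v]), 100.0)[0] == expected

    def test_aliasing_idempotent_on_its_output(self, ventricle_phantoms):
        fld, _, _ = ventricle_phantoms["systolic_dominant"]
        hot = fld.copy()
        hot.values = hot.values * 2.5  # force some speeds past venc
        once = k.inject_aliasing(hot)
        twice = k.inject_aliasing(once)
        np.testing.assert_array_equal(once.values, twice.values)
        assert np.all(once.values >= -hot.metadata.venc)
        assert np.all(once.values < hot.metadata.venc)

    def test_injectors_do_not_touch_source_field(self, uniform_phantom):
        fld, _, _ = uniform_phantom
        before = fld.values.copy()
        k.inject_eddy_offset(fld, np.ones((3, 4)))
        k.inject_aliasing(fld)
        k.inject_noise(fld, 1.0, seed=0)
        np.testing.assert_array_equal(fld.values, before)

    def test_wrap_sites_only_where_speed_exceeds_venc(self):
        fld, _, truth = k.make_ventricle_phantom(
            "systolic_dominant", n_phases=20, seed=3,
            peak_sys_mj=30.0, peak_dia_mj=18.0)
        k.inject_aliasing(fld, truth)
        assert truth.wrap_sites  # corruption actually happened
        for (p, x, y, z, c) in truth.wrap_sites:
            assert abs(fld.values[p, x, y, z, c]) >= fld.metadata.venc


class TestCohortSimulation:
    def _tiny_spec(self, seed, sd=0.0):
        g = k.GroupParams(peak_sys_ke_sv=(0.04, sd), peak_dia_ke_sv=(0.03, sd),
                          edvi=(70.0, 0.0), ef=(50.0, 0.0), bsa=(1.0, 0.0),
                          hr_range=(80.0, 80.0))
        return k.CohortSpec(n_per_group=2, groups={"fontan": g, "control": g},
                            seed=seed, grid=(24, 24, 24),
                            n_phases_acquired=12, inject_corruptions=False)

    def test_zero_sd_gives_identical_truth_peaks(self):
        subs = k.simulate_cohort(self._tiny_spec(seed=1))
        vals = [s.truth.extras["peak_sys_ke_sv"] for s in subs]
        assert len(set(vals)) == 1

    def test_seed_determinism_and_sensitivity(self):
        a = k.simulate_cohort(self._tiny_spec(seed=1, sd=0.01))
        b = k.simulate_cohort(self._tiny_spec(seed=1, sd=0.01))
        c = k.simulate_cohort(self._tiny_spec(seed=2, sd=0.01))
        np.testing.assert_array_equal(a[0].field.values, b[0].field.values)
        assert (a[0].truth.extras["peak_sys_ke_sv"]
                != c[0].truth.extras["peak_sys_ke_sv"])

    def test_truth_realizes_drawn_ke_sv(self):
        subs = k.simulate_cohort(self._tiny_spec(seed=3, sd=0.005))
        for s in subs:
            sv = s.truth.extras["sv_ml"]
            # up to the (tiny) overlap of the systolic and diastolic bumps
            assert (s.truth.true_ke_curve.max() / sv
                    == pytest.approx(max(s.truth.extras["peak_sys_ke_sv"],
                                         s.truth.extras["peak_dia_ke_sv"]),
                                     rel=1e-4))
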