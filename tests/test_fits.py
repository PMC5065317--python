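"""Gating-curve fits: Boltzmann, derivative-Gaussian, leak, valence, decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hvgating import (
    IVTable,
    UndefinedPointError,
    boltzmann,
    conductance_from_current,
    decompose_two_conductances,
    estimate_leak,
    fill_g_step,
    fit_boltzmann,
    fit_boltzmann_shared,
    fit_gaussian_peak,
    fit_line,
    gating_valence,
    normalize_at,
    numeric_derivative,
    subtract_leak,
    thermal_voltage,
)
from hvgating.fits import gaussian_peak


def iv_from(v, i_step, i_tail=None, v_tail=None):
    frame = pd.DataFrame(
        {
            "v_step": v,
            "i_step": i_step,
            "i_tail": 0.0 if i_tail is None else i_tail,
            "i_tail_tau": 1.0,
            "g_step": np.nan,
        }
    )
    prov = {} if v_tail is None else {"v_tail": v_tail}
    return IVTable(frame, provenance=prov)


class TestConductanceTransform:
    def test_arithmetic(self):
        assert conductance_from_current(0.0, -100.0, 0.0) == 0.0
        assert conductance_from_current(-1000.0, -100.0, 0.0) == pytest.approx(10.0)

    def test_reversal_guard(self):
        with pytest.raises(UndefinedPointError):
            conductance_from_current(5.0, 58.2, 58.2)
        with pytest.raises(UndefinedPointError):
            conductance_from_current(5.0, 58.5, 58.2)  # inside 1 mV guard

    def test_fill_flags_guarded_rows(self):
        v = np.arange(-20.0, 21.0, 10.0)
        iv = fill_g_step(iv_from(v, 2.0 * v), e_rev=0.0)
        assert np.isnan(iv.frame.loc[iv.frame.v_step == 0.0, "g_step"]).all()
        assert iv.provenance["undefined_rows"] == [0.0]
        ok = iv.frame["g_step"].dropna()
        assert np.allclose(ok, 2.0)


class TestLeak:
    def test_pure_ohmic_recovered_exactly(self):
        v = np.arange(-100.0, 101.0, 10.0)
        leak = estimate_leak(iv_from(v, 1.5 * v), window=(0.0, 50.0))
        assert leak.g_leak == pytest.approx(1.5, abs=1e-12)
        assert leak.i_offset == pytest.approx(0.0, abs=1e-9)

    def test_subtracting_own_fit_zeroes_residuals(self):
        v = np.arange(-100.0, 101.0, 10.0)
        iv = iv_from(v, 1.5 * v + 3.0)
        out = subtract_leak(iv, estimate_leak(iv, window=(-100.0, 100.0)))
        assert np.allclose(out.frame["i_step"], 0.0, atol=1e-9)

    def test_zero_leak_subtraction_is_identity(self):
        from hvgating import LeakEstimate

        v = np.arange(-50.0, 51.0, 10.0)
        iv = iv_from(v, v**2)
        out = subtract_leak(iv, LeakEstimate(g_leak=0.0, i_offset=0.0, window=(0.0, 50.0)))
        assert np.array_equal(out.frame["i_step"], iv.frame["i_step"])

    def test_tail_leak_is_constant_at_tail_voltage(self):
        from hvgating import LeakEstimate

        v = np.arange(-50.0, 51.0, 10.0)
        iv = iv_from(v, 1.5 * v, i_tail=-100.0, v_tail=-90.0)
        out = subtract_leak(iv, LeakEstimate(g_leak=1.5, i_offset=0.0, window=(0, 50)))
        assert np.allclose(out.frame["i_tail"], -100.0 - 1.5 * (-90.0))

    def test_plateau_window_recovers_injected_leak(self, symmetric_ph):
        from hvgating import reference_parameter_sets, simulate_sweep_set, measure_sweep_set
        from hvgating.pipeline import default_protocol

        specs, cond = reference_parameter_sets()["R1H-N4R"]
        sweeps = simulate_sweep_set(specs, default_protocol("R1H-N4R"), cond)
        iv = measure_sweep_set(sweeps, i_step_policy="steady")
        leak = estimate_leak(iv, window=(10.0, 60.0))
        assert leak.g_leak == pytest.approx(1.5, rel=0.05)

    def test_too_few_points_rejected(self):
        v = np.arange(-100.0, 101.0, 50.0)
        with pytest.raises(ValueError):
            estimate_leak(iv_from(v, 1.5 * v), window=(0.0, 10.0))


class TestBoltzmannFit:
    v = np.arange(-100.0, 151.0, 5.0)

    @pytest.mark.parametrize("polarity", ["depolarization", "hyperpolarization"])
    def test_noiseless_recovery(self, polarity):
        y = boltzmann(self.v, 26.3, 16.3, 8.0, -1.0, polarity)
        fit = fit_boltzmann(self.v, y, polarity=polarity)
        assert fit.v_half == pytest.approx(26.3, rel=1e-6)
        assert fit.slope_dx == pytest.approx(16.3, rel=1e-6)
        assert fit.y_max == pytest.approx(8.0, rel=1e-6)
        assert fit.y_min == pytest.approx(-1.0, rel=1e-6)

    def test_fixed_v_half_held_exactly(self):
        v = np.arange(-240.0, 41.0, 10.0)
        y = boltzmann(v, -170.0, 42.1, 4.6, 0.0, "hyperpolarization")
        fit = fit_boltzmann(v, y, polarity="hyperpolarization",
                            constraints={"v_half": -189.0})
        assert fit.v_half == -189.0
        assert "v_half" in fit.constraints

    def test_shared_slope_across_datasets(self):
        vs = np.arange(-60.0, 161.0, 10.0)
        datasets = [
            (vs, boltzmann(vs, vh, 16.2, 1.0, 0.0, "depolarization"))
            for vh in (66.3, 25.0, -15.7)
        ]
        fits = fit_boltzmann_shared(datasets, polarity="depolarization", shared=("slope_dx",))
        dxs = {round(f.slope_dx, 6) for f in fits}
        assert len(dxs) == 1
        assert fits[0].slope_dx == pytest.approx(16.2, rel=1e-6)
        assert [round(f.v_half, 1) for f in fits] == [66.3, 25.0, -15.7]

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError):
            fit_boltzmann([0.0, 10.0], [0.1, 0.9])


class TestNumericDerivative:
    def test_linear_gives_constant_slope(self):
        v = np.array([-50.0, -20.0, 0.0, 35.0, 80.0])  # nonuniform grid
        d = numeric_derivative(v, 0.7 * v + 2.0)
        assert np.allclose(d, 0.7)

    def test_constant_gives_zero(self):
        v = np.arange(0.0, 50.0, 10.0)
        assert np.allclose(numeric_derivative(v, np.full_like(v, 3.3)), 0.0)

    def test_peak_matches_analytic_quarter_rule(self):
        v = np.arange(-150.0, 151.0, 1.0)
        g = boltzmann(v, 10.0, 16.3, 5.0, 1.0, "depolarization")
        d = numeric_derivative(v, g)
        assert d.max() == pytest.approx((5.0 - 1.0) / (4 * 16.3), rel=0.01)

    def test_duplicate_voltages_rejected(self):
        with pytest.raises(ValueError):
            numeric_derivative([0.0, 0.0, 10.0], [1.0, 2.0, 3.0])


class TestGaussianPeak:
    def test_exact_gaussian_recovered(self):
        v = np.arange(-100.0, 101.0, 5.0)
        y = gaussian_peak(v, 0.3, 12.0, 55.0, -20.0)
        fit = fit_gaussian_peak(v, y)
        assert fit.baseline == pytest.approx(0.3, abs=1e-9)
        assert fit.area_a == pytest.approx(12.0, rel=1e-9)
        assert fit.width_omega == pytest.approx(55.0, rel=1e-9)
        assert fit.v_peak == pytest.approx(-20.0, abs=1e-9)

    @pytest.mark.parametrize("v_half, polarity", [(20.0, "depolarization"),
                                                  (-100.0, "hyperpolarization")])
    def test_boltzmann_derivative_peaks_at_midpoint(self, v_half, polarity):
        v = np.arange(v_half - 150.0, v_half + 151.0, 10.0)
        g = boltzmann(v, v_half, 26.0, 1.0, 0.0, polarity)
        d = np.abs(numeric_derivative(v, g))
        fit = fit_gaussian_peak(v, d)
        assert fit.v_peak == pytest.approx(v_half, abs=2.0)

    def test_fixed_omega_held(self):
        v = np.arange(-100.0, 101.0, 10.0)
        g = boltzmann(v, 20.0, 26.0, 1.0, 0.0, "depolarization")
        fit = fit_gaussian_peak(v, np.abs(numeric_derivative(v, g)), fixed_omega=83.2)
        assert fit.width_omega == 83.2
        assert "width_omega" in fit.constraints

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_peak([0, 1, 2, 3], [0, 1, 0, 0])


class TestGatingValence:
    @pytest.mark.parametrize("dx, expected", [(42.1, 0.60), (35.4, 0.71)])
    def test_reference_values(self, dx, expected):
        assert round(gating_valence(dx), 2) == expected

    def test_definitional_identity(self):
        vt = thermal_voltage(293.15)
        assert gating_valence(vt) == pytest.approx(1.0)

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_round_trip_through_slope(self, z):
        dx = thermal_voltage(293.15) / z
        assert gating_valence(dx) == pytest.approx(z, rel=1e-12)

    def test_nonpositive_dx_rejected(self):
        with pytest.raises(ValueError):
            gating_valence(0.0)


class TestFitLine:
    def test_collinear_points_perfect_correlation(self):
        fit = fit_line([0, 1, 2, 3], [5, 3, 1, -1])
        assert fit.pearson_r == pytest.approx(-1.0)
        assert fit.slope == pytest.approx(-2.0)

    def test_ph_slope_fixtures(self):
        # agreement at the printed precision (half a unit in the last digit)
        slope_sh = fit_line([5.5, 6.5, 7.5], [-157.4, -197.6, -245.7]).slope
        assert abs(slope_sh - (-44.2)) <= 0.05 + 1e-9
        slope_aq = fit_line([5.5, 6.5, 7.5], [66.3, 25.0, -15.7]).slope
        assert abs(slope_aq - (-41.0)) <= 0.05 + 1e-9

    def test_vpeak_vthr_correlation_fixture(self):
        fit = fit_line([-25.0, -20.7, 40.0, 80.0], [-183.5, -188.9, -187.9, -197.5])
        assert round(fit.pearson_r, 2) == -0.84

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_line([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    @given(
        st.floats(min_value=0.1, max_value=50.0),
        st.floats(min_value=-100.0, max_value=100.0),
    )
    def test_pearson_invariant_to_affine_rescaling(self, scale, offset):
        xs = np.array([-25.0, -20.7, 40.0, 80.0])
        ys = np.array([-183.5, -188.9, -187.9, -197.5])
        r0 = fit_line(xs, ys).pearson_r
        r1 = fit_line(scale * xs + offset, ys).pearson_r
        r2 = fit_line(xs, scale * ys + offset).pearson_r
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert r2 == pytest.approx(r0, abs=1e-9)


class TestTwoConductanceDecomposition:
    v = np.arange(-240.0, 151.0, 10.0)

    def u_shape(self, g_sh=4.6, g_aq=22.2):
        return (
            boltzmann(self.v, -189.0, 42.1, g_sh, 0.0, "hyperpolarization")
            + boltzmann(self.v, 29.4, 24.9, g_aq, 0.0, "depolarization")
        )

    def test_noiseless_six_parameter_recovery(self):
        sh, aq, ratio = decompose_two_conductances(self.v, self.u_shape(), seed=1)
        assert sh.v_half == pytest.approx(-189.0, rel=1e-4)
        assert sh.slope_dx == pytest.approx(42.1, rel=1e-4)
        assert sh.y_max == pytest.approx(4.6, rel=1e-4)
        assert aq.v_half == pytest.approx(29.4, rel=1e-4)
        assert aq.slope_dx == pytest.approx(24.9, rel=1e-4)
        assert aq.y_max == pytest.approx(22.2, rel=1e-4)

    def test_max_conductance_ratio(self):
        _, _, ratio = decompose_two_conductances(self.v, self.u_shape(), seed=1)
        assert round(ratio, 1) == 4.8

    def test_single_component_flags_collapse(self):
        g = boltzmann(self.v, 29.4, 24.9, 22.2, 0.0, "depolarization")
        sh, aq, _ = decompose_two_conductances(self.v, g, seed=1)
        assert "collapsed" in sh.flags
        assert aq.y_max == pytest.approx(22.2, rel=1e-3)


class TestRigidShiftEquivariance:
    v = np.arange(-150.0, 151.0, 10.0)

    @pytest.mark.parametrize("delta", [-60.0, 35.0])
    def test_midpoint_estimators_shift_with_data(self, delta):
        y0 = boltzmann(self.v, 10.0, 20.0, 1.0, 0.0, "depolarization")
        b0 = fit_boltzmann(self.v, y0)
        b1 = fit_boltzmann(self.v + delta, y0)
        assert b1.v_half - b0.v_half == pytest.approx(delta, abs=1e-6)
        assert b1.slope_dx == pytest.approx(b0.slope_dx, rel=1e-8)
        assert b1.y_max == pytest.approx(b0.y_max, rel=1e-8)

        d0 = np.abs(numeric_derivative(self.v, y0))
        g0 = fit_gaussian_peak(self.v, d0)
        g1 = fit_gaussian_peak(self.v + delta, d0)
        assert g1.v_peak - g0.v_peak == pytest.approx(delta, abs=1e-6)
        assert g1.width_omega == pytest.approx(g0.width_omega, rel=1e-8)


class TestNormalize:
    def test_normalize_at_reference_voltage(self):
        v = np.arange(-100.0, 101.0, 10.0)
        y = boltzmann(v, 0.0, 20.0, 6.0, 0.0, "depolarization")
        n = normalize_at(v, y, 100.0)
        assert n[-1] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            normalize_at(v, np.zeros_like(v), 100.0)
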