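import numpy as np
import pytest
from hypothesis import given, strategies as st

import reesfit as rf
from reesfit.exceptions import ModelEvaluationError, ValidationError


class TestQubes:
    def test_zero_amplitude_is_flat(self):
        p = rf.QubesParams(csm0=350.0, amplitude=0.0, curvature=0.1, reference_lambda=292.0)
        lam = np.arange(292.0, 320.0)
        np.testing.assert_allclose(rf.qubes_csm(p, lam), 350.0)

    def test_reference_wavelength_value(self):
        p = rf.QubesParams(csm0=350.0, amplitude=2.5, curvature=0.1, reference_lambda=292.0)
        assert rf.qubes_csm(p, 292.0) == pytest.approx(352.5)

    def test_direct_arithmetic(self):
        # CSM0=350, A=1, Rc=0.1/nm, 10 nm above reference -> 350 + e
        p = rf.QubesParams(csm0=350.0, amplitude=1.0, curvature=0.1, reference_lambda=292.0)
        assert rf.qubes_csm(p, 302.0) == pytest.approx(352.71828182845906, abs=1e-10)

    def test_overflow_raises(self):
        p = rf.QubesParams(csm0=350.0, amplitude=1.0, curvature=100.0, reference_lambda=292.0)
        with pytest.raises(ModelEvaluationError):
            rf.qubes_csm(p, 310.0)


class TestBoltzmannFraction:
    def test_zero_gap_is_half(self):
        assert rf.boltzmann_fraction(0.0, 298.15) == pytest.approx(0.5, abs=1e-15)

    def test_unit_reduced_gap(self):
        rt = rf.GAS_CONSTANT * 298.15
        assert rf.boltzmann_fraction(rt, 298.15) == pytest.approx(
            1.0 / (1.0 + np.e), abs=1e-12
        )

    def test_saturating_limits(self):
        assert rf.boltzmann_fraction(-1e9, 298.15) == pytest.approx(1.0)
        assert rf.boltzmann_fraction(1e9, 298.15) == pytest.approx(0.0, abs=1e-300)

    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(ValidationError):
            rf.boltzmann_fraction(0.0, -5.0)


class TestDeltaG:
    def test_zero_at_midpoint(self, solution_truth):
        assert rf.delta_g_at(solution_truth, solution_truth.lambda50) == 0.0

    def test_direct_arithmetic(self):
        p = rf.ThermoParams(csm_fc=355.0, csm_r=398.0, m=0.005, lambda50=300.0)
        assert rf.delta_g_at(p, 310.0) == pytest.approx(-0.05, abs=1e-15)

    def test_slope_is_minus_m(self, solution_truth):
        lam = np.arange(292.0, 320.0)
        dg = np.asarray(rf.delta_g_at(solution_truth, lam))
        np.testing.assert_allclose(np.diff(dg), -solution_truth.m, rtol=1e-12)


class TestThermoCSM:
    def test_midpoint_is_baseline_mean(self, solution_truth):
        p = solution_truth
        assert rf.thermo_csm(p, p.lambda50) == pytest.approx(
            0.5 * (p.csm_fc + p.csm_r), abs=1e-12
        )

    def test_asymptotes(self, solution_truth):
        p = solution_truth
        assert rf.thermo_csm(p, -1e6) == pytest.approx(p.csm_fc, abs=1e-9)
        assert rf.thermo_csm(p, 1e6) == pytest.approx(p.csm_r, abs=1e-9)

    def test_unit_logistic_argument(self):
        # x = 1 exactly: (355 + 398 e)/(1 + e)
        rt = rf.GAS_CONSTANT * 298.15
        p = rf.ThermoParams(csm_fc=355.0, csm_r=398.0, m=rt, lambda50=300.0)
        assert rf.thermo_csm(p, 301.0) == pytest.approx(386.4355188810902, abs=1e-9)

    @given(
        m=st.floats(1.0, 2000.0),
        lambda50=st.floats(300.0, 360.0),
        csm_fc=st.floats(340.0, 370.0),
        gap=st.floats(0.0, 60.0),
    )
    def test_consistency_with_population_mix(self, m, lambda50, csm_fc, gap):
        p = rf.ThermoParams(csm_fc=csm_fc, csm_r=csm_fc + gap, m=m, lambda50=lambda50)
        lam = np.linspace(280.0, 420.0, 41)
        frac = rf.boltzmann_fraction(rf.delta_g_at(p, lam), p.temperature)
        mix = p.csm_fc * (1 - frac) + p.csm_r * frac
        np.testing.assert_allclose(rf.thermo_csm(p, lam), mix, rtol=1e-12, atol=1e-12)

    def test_monotone_and_bounded(self, solution_truth):
        lam = np.linspace(250.0, 450.0, 500)
        csm = np.asarray(rf.thermo_csm(solution_truth, lam))
        assert np.all(np.diff(csm) >= 0)
        assert csm.min() >= solution_truth.csm_fc - 1e-9
        assert csm.max() <= solution_truth.csm_r + 1e-9

    def test_literal_form_upper_asymptote_is_sum(self, solution_truth):
        p = solution_truth
        val = rf.thermo_csm(p, 1e6, literal_form=True)
        assert val == pytest.approx(p.csm_fc + p.csm_r, abs=1e-6)

    def test_rejects_inverted_baselines(self):
        with pytest.raises(ValidationError):
            rf.ThermoParams(csm_fc=400.0, csm_r=390.0, m=300.0, lambda50=315.0)


class TestMeltModelFunctions:
    def test_ku_at_tm_is_one(self):
        for dh in (1e3, 250e3, 5e5):
            assert rf.equilibrium_constant(378.65, 378.65, dh) == pytest.approx(1.0, abs=1e-15)

    def test_zero_enthalpy_gives_unit_ku(self):
        t = np.linspace(280.0, 380.0, 11)
        np.testing.assert_allclose(rf.equilibrium_constant(t, 330.0, 0.0), 1.0)

    def test_ku_direct_arithmetic(self):
        # exp(-250e3 * (1 - 368.65/378.65) / (8.314 * 368.65)); 10 K below
        # Tm the protein is predominantly folded
        expected = np.exp(-250e3 * (1 - 368.65 / 378.65) / (8.314 * 368.65))
        got = rf.equilibrium_constant(368.65, 378.65, 250e3)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.0 / 8.62063860070289, rel=1e-12)
        # the sign-dropped variant inverts the constant
        literal = rf.equilibrium_constant(368.65, 378.65, 250e3, literal_sign=True)
        assert literal == pytest.approx(8.62063860070289, rel=1e-12)

    def test_overflow_saturates(self):
        assert np.isfinite(rf.equilibrium_constant(200.0, 400.0, 5e6))
        assert rf.fraction_unfolded(200.0, 400.0, 5e6) == pytest.approx(0.0, abs=1e-200)

    def test_signal_at_tm_with_zero_unfolded_limb(self):
        # Ku = 1, unfolded baseline zero -> half the folded baseline
        tm, b_f, a_f = 350.0, -20.0, 0.05
        assert rf.melt_signal(tm, tm, 300e3, b_f, a_f) == pytest.approx(
            0.5 * (b_f + a_f * tm), rel=1e-12
        )

    def test_infinite_enthalpy_limit_is_folded_baseline(self):
        val = rf.melt_signal(340.0, 350.0, 5e6, -20.0, 0.05, -2.0, 0.01)
        assert val == pytest.approx(-20.0 + 0.05 * 340.0, rel=1e-9)

    def test_unit_ku_is_baseline_mean(self):
        # dH = 0 makes Ku = 1 at every T
        t = np.linspace(290.0, 370.0, 9)
        got = rf.melt_signal(t, 330.0, 0.0, -20.0, 0.02, -2.0, 0.002)
        mean = 0.5 * ((-20.0 + 0.02 * t) + (-2.0 + 0.002 * t))
        np.testing.assert_allclose(got, mean, rtol=1e-12)

    def test_signal_monotone_between_monotone_baselines(self):
        t = np.linspace(280.0, 380.0, 201)
        y = np.asarray(rf.melt_signal(t, 330.0, 300e3, -20.0, 0.02, -2.0, 0.002))
        assert np.all(np.diff(y) > 0)
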