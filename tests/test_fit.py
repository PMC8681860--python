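import numpy as np
import pytest

import reesfit as rf
from reesfit.csm import CSMCurve
from reesfit.exceptions import ValidationError
from reesfit.fit import REESResults
from reesfit.studies import ACCESSIBLE_GRID, EXTENDED_GRID


class TestThermoFit:
    def test_noiseless_recovery_with_fixed_csm_r(self, solution_truth):
        curve = rf.generate_csm_curve(solution_truth, ACCESSIBLE_GRID)
        res = rf.fit_thermo(curve, fix_csm_r=solution_truth.csm_r)
        assert res.params.m == pytest.approx(solution_truth.m, rel=1e-6)
        assert res.params.csm_fc == pytest.approx(solution_truth.csm_fc, rel=1e-6)
        assert res.params.lambda50 == pytest.approx(solution_truth.lambda50, rel=1e-6)
        assert res.fixed["csm_r"] and res.bse["csm_r"] is None

    def test_noiseless_recovery_free_csm_r_extended_window(self, solution_truth):
        curve = rf.generate_csm_curve(solution_truth, EXTENDED_GRID)
        res = rf.fit_thermo(curve)
        assert res.params.csm_r == pytest.approx(solution_truth.csm_r, rel=1e-6)
        assert res.params.m == pytest.approx(solution_truth.m, rel=1e-5)

    def test_noisy_recovery_bias(self, solution_truth):
        # median |m_hat - m| / m < 10% over replicate noisy curves
        rng = np.random.default_rng(42)
        errs = [
            abs(
                rf.fit_thermo(
                    rf.generate_csm_curve(solution_truth, ACCESSIBLE_GRID, 0.1, rng),
                    fix_csm_r=solution_truth.csm_r,
                ).params.m
                - solution_truth.m
            )
            for _ in range(30)
        ]
        assert np.median(errs) / solution_truth.m < 0.10

    def test_too_few_points_rejected(self):
        curve = CSMCurve([292.0, 293.0, 294.0], [355.0, 355.5, 356.0], temperature=298.15)
        with pytest.raises(ValidationError):
            rf.REESModel(curve)

    def test_weighted_equals_unweighted_for_equal_weights(self, solution_truth):
        base = rf.generate_csm_curve(solution_truth, ACCESSIBLE_GRID, 0.1, seed=9)
        weighted = CSMCurve(
            base.excitation_wavelengths,
            base.csm_values,
            np.full(len(base), 0.37),
            temperature=298.15,
        )
        r1 = rf.fit_thermo(base, fix_csm_r=solution_truth.csm_r)
        r2 = rf.fit_thermo(weighted, fix_csm_r=solution_truth.csm_r)
        assert r1.params.m == pytest.approx(r2.params.m, rel=1e-6)
        assert r1.params.csm_fc == pytest.approx(r2.params.csm_fc, rel=1e-8)

    def test_truncation_inflates_csm_r_uncertainty(self, solution_truth):
        full = rf.generate_csm_curve(solution_truth, EXTENDED_GRID, 0.1, seed=3)
        mask = full.excitation_wavelengths <= 310.0
        trunc = CSMCurve(
            full.excitation_wavelengths[mask],
            full.csm_values[mask],
            temperature=298.15,
        )
        se_full = rf.fit_thermo(full).bse["csm_r"]
        se_trunc = rf.fit_thermo(trunc).bse["csm_r"]
        assert se_trunc > se_full

    def test_bootstrap_errors_agree_with_covariance(self, solution_truth):
        curve = rf.generate_csm_curve(solution_truth, ACCESSIBLE_GRID, 0.1, seed=2)
        model = rf.REESModel(curve, fix_csm_r=solution_truth.csm_r)
        cov = model.fit()
        boot = model.fit(bootstrap=100)
        # same point estimate; errors within a factor two; fixed stays fixed
        assert boot.params.m == cov.params.m
        assert 0.5 < boot.bse["m"] / cov.bse["m"] < 2.0
        assert boot.bse["csm_r"] is None

    def test_fixed_csm_r_sensitivity_is_smooth_and_bounded(self, protein_truth):
        curve = rf.generate_csm_curve(protein_truth, ACCESSIBLE_GRID)
        m_ref = rf.fit_thermo(curve, fix_csm_r=protein_truth.csm_r).params.m
        grid = np.arange(387.0, 441.0, 6.0)
        ms, fcs = [], []
        for fixed in grid:
            res = rf.fit_thermo(curve, fix_csm_r=float(fixed))
            ms.append(res.params.m)
            fcs.append(res.params.csm_fc)
        ms = np.asarray(ms)
        assert np.max(np.abs(ms - m_ref)) / m_ref < 0.25
        assert np.max(np.abs(np.diff(ms))) / m_ref < 0.1  # no jumps
        assert np.max(np.abs(np.asarray(fcs) - protein_truth.csm_fc)) < 0.05


class TestGlobalFit:
    def test_single_curve_matches_plain_fit(self, solution_truth):
        curve = rf.generate_csm_curve(solution_truth, ACCESSIBLE_GRID, 0.1, seed=17)
        single = rf.fit_thermo(curve)
        joint = rf.fit_thermo_global([curve])
        assert joint.csm_r == pytest.approx(single.params.csm_r, abs=1e-10)
        assert joint.results[0].params.m == pytest.approx(single.params.m, abs=1e-10)

    def test_copies_of_one_curve_match_single_fit(self, solution_truth):
        curve = rf.generate_csm_curve(solution_truth, EXTENDED_GRID, 0.1, seed=23)
        single = rf.fit_thermo(curve)
        joint = rf.fit_thermo_global([curve, curve, curve])
        for member in joint.results:
            assert member.params.m == pytest.approx(single.params.m, rel=1e-5)
        assert joint.csm_r == pytest.approx(single.params.csm_r, rel=1e-5)

    def test_shared_csm_r_recovered(self, solution_truth):
        rng = np.random.default_rng(5)
        curves = [
            rf.generate_csm_curve(
                rf.ThermoParams(csm_fc=fc, csm_r=398.0, m=m, lambda50=l50),
                EXTENDED_GRID,
                0.1,
                rng,
            )
            for fc, m, l50 in [(352, 250, 312), (355, 300, 314), (358, 350, 316),
                               (361, 400, 318), (364, 450, 320)]
        ]
        res = rf.fit_thermo_global(curves)
        assert res.csm_r == pytest.approx(398.0, abs=0.25)
        assert res.csm_r_stderr is not None and res.csm_r_stderr > 0
        assert all(r.shared == ("csm_r",) for r in res.results)
        assert all(r.params.csm_r == res.csm_r for r in res.results)

    def test_incompatible_grids_accepted(self, solution_truth):
        a = rf.generate_csm_curve(solution_truth, np.arange(292.0, 311.0), 0.05, seed=1)
        b = rf.generate_csm_curve(solution_truth, np.arange(295.0, 338.0, 2.0), 0.05, seed=2)
        res = rf.fit_thermo_global([a, b])
        assert len(res.results) == 2


class TestQubesFit:
    def test_noiseless_recovery(self):
        truth = rf.QubesParams(csm0=354.0, amplitude=2.0, curvature=0.15, reference_lambda=292.0)
        lam = np.arange(292.0, 311.0)
        curve = CSMCurve(lam, np.asarray(rf.qubes_csm(truth, lam)), temperature=298.15)
        res = rf.fit_qubes(curve)
        assert res.params.csm0 == pytest.approx(truth.csm0, rel=1e-6)
        assert res.params.amplitude == pytest.approx(truth.amplitude, rel=1e-6)
        assert res.params.curvature == pytest.approx(truth.curvature, rel=1e-6)

    def test_flat_curve_gives_zero_amplitude(self):
        # a flat curve is a degenerate ridge (any csm0 + A summing to the
        # level fits as curvature -> 0), so only approximate recovery is
        # meaningful
        lam = np.arange(292.0, 302.0)
        curve = CSMCurve(lam, np.full(lam.size, 356.0), temperature=298.15)
        res = rf.fit_qubes(curve)
        assert res.params.amplitude == pytest.approx(0.0, abs=0.01)
        assert res.params.csm0 == pytest.approx(356.0, abs=0.01)
        assert res.rms < 1e-4

    def test_noisy_parameter_bias_is_small(self):
        truth = rf.QubesParams(csm0=354.0, amplitude=2.0, curvature=0.15, reference_lambda=292.0)
        lam = np.arange(292.0, 311.0)
        clean = np.asarray(rf.qubes_csm(truth, lam))
        rng = np.random.default_rng(8)
        est = []
        for _ in range(50):
            curve = CSMCurve(lam, clean + rng.normal(0, 0.1, lam.size), temperature=298.15)
            est.append(rf.fit_qubes(curve).params.amplitude)
        assert abs(np.median(est) - truth.amplitude) / truth.amplitude < 0.05


class TestComparisons:
    @staticmethod
    def _result(m, se):
        params = rf.ThermoParams(csm_fc=355.0, csm_r=398.0, m=m, lambda50=315.0)
        return REESResults(
            params=params, bse={"m": se}, fixed={"csm_r": True}, rms=0.0,
            n_points=19, n_starts_converged=5, n_starts=5, success=True,
        )

    def test_self_difference_is_zero_with_quadrature_error(self):
        a = self._result(0.005, 0.001)
        ddg, err = rf.delta_delta_g(a, a)
        assert ddg == 0.0
        assert err == pytest.approx(np.sqrt(2) * 0.001, rel=1e-12)

    def test_quadrature_arithmetic(self):
        a = self._result(0.013, 0.004)
        b = self._result(0.003, 0.001)
        ddg, err = rf.delta_delta_g(a, b)
        assert ddg == pytest.approx(0.010, abs=1e-15)
        assert err == pytest.approx(0.00412310562561766, rel=1e-12)

    def test_antisymmetry(self):
        a = self._result(0.013, 0.004)
        b = self._result(0.003, 0.001)
        assert rf.delta_delta_g(a, b)[0] == -rf.delta_delta_g(b, a)[0]


class TestTemperatureTrend:
    def test_exact_line_recovered_without_breakpoint(self):
        t = np.arange(288.15, 338.15, 5.0)
        m = 0.010 - 1e-4 * (t - t[0])
        trend = rf.temperature_trend(list(zip(t, m)), allow_breakpoint=True)
        assert trend.slope == pytest.approx(-1e-4, rel=1e-10)
        assert not trend.has_breakpoint

    def test_constant_m_has_zero_slope_within_ci(self):
        rng = np.random.default_rng(12)
        t = np.arange(288.15, 338.15, 5.0)
        m = 0.010 + rng.normal(0, 2e-4, t.size)
        trend = rf.temperature_trend(list(zip(t, m)))
        assert abs(trend.slope) < 2 * trend.slope_stderr

    def test_two_segment_breakpoint_recovered(self):
        t = np.arange(288.15, 349.0, 5.0)
        tb = 328.15
        m = np.where(
            t <= tb,
            0.010 - 0.1e-3 * (t - t[0]),
            0.010 - 0.1e-3 * (tb - t[0]) - 0.25e-3 * (t - tb),
        )
        rng = np.random.default_rng(3)
        trend = rf.temperature_trend(
            list(zip(t, m + rng.normal(0, 1e-4, t.size))), allow_breakpoint=True
        )
        assert trend.has_breakpoint
        assert abs(trend.breakpoint - tb) <= 5.0
        assert trend.slopes[1] < trend.slopes[0] < 0

    def test_accepts_fit_results(self, solution_truth):
        entries = []
        for i, t in enumerate((288.15, 298.15, 308.15)):
            res = TestComparisons._result(0.010 - 1e-4 * i, 0.001)
            entries.append((t, res))
        trend = rf.temperature_trend(entries)
        assert trend.slope == pytest.approx(-1e-5, rel=1e-9)

    def test_preconditions(self):
        with pytest.raises(ValidationError):
            rf.temperature_trend([(288.0, 0.01), (298.0, 0.009)])
        four = [(288.0, 0.01), (293.0, 0.009), (298.0, 0.008), (303.0, 0.007)]
        with pytest.raises(ValidationError):
            rf.temperature_trend(four, allow_breakpoint=True)
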