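"""Parameter-recovery simulation studies.

Each function simulates data from known ground truth with the
:mod:`reesfit.simulate` generator, runs the corresponding estimator, and
summarises recovery.  These studies back the package's validation suite;
they are also useful templates for power analyses when planning real
experiments.  All randomness flows from the caller's seed.
"""

from __future__ import annotations

import numpy as np

from .fit import REESModel, GlobalREESModel, temperature_trend
from .io import CELSIUS_OFFSET
from .melt import MeltModel
from .models import ThermoParams
from .simulate import DEFAULT_TRUTH, generate_csm_curve, generate_melt_curve

#: excitation grids: the routinely accessible window, and the extended
#: window of a complete (saturating) red-edge experiment
ACCESSIBLE_GRID = np.arange(292.0, 311.0)
EXTENDED_GRID = np.arange(292.0, 341.0)

#: Protein-like ground truth: same baselines as the solution-tryptophan
#: default but with the transition midpoint well beyond the accessible
#: excitation window, so the CSM rises only ~2 nm across 292-310 nm — the
#: shape protein red-edge curves show.
PROTEIN_TRUTH = ThermoParams(
    csm_fc=355.0, csm_r=398.0, m=300.0, lambda50=335.0, temperature=298.15
)


def m_recovery_study(
    n_curves: int = 100,
    noise_sd: float = 0.1,
    truth: ThermoParams = DEFAULT_TRUTH,
    lambda_ex: np.ndarray = ACCESSIBLE_GRID,
    seed: int = 0,
) -> dict:
    """Recovery of m and CSM_FC with the relaxed baseline fixed at truth.

    Simulates ``n_curves`` CSM curves (truth + Gaussian noise of
    ``noise_sd`` nm), fits each with ``csm_r`` fixed at its true value, and
    reports median absolute and relative errors of the free parameters.
    """
    rng = np.random.default_rng(seed)
    err_m, err_fc = [], []
    for _ in range(n_curves):
        curve = generate_csm_curve(truth, lambda_ex, noise_sd, rng)
        res = REESModel(curve, fix_csm_r=truth.csm_r).fit()
        err_m.append(res.params.m - truth.m)
        err_fc.append(res.params.csm_fc - truth.csm_fc)
    err_m = np.abs(err_m)
    err_fc = np.abs(err_fc)
    return {
        "n": n_curves,
        "noise_sd": noise_sd,
        "median_rel_err_m": float(np.median(err_m) / truth.m),
        "median_rel_err_csm_fc": float(np.median(err_fc) / truth.csm_fc),
        "median_abs_err_m": float(np.median(err_m)),
        "median_abs_err_csm_fc": float(np.median(err_fc)),
    }


def global_fit_coverage_study(
    n_experiments: int = 100,
    n_curves: int = 5,
    noise_sd: float = 0.1,
    csm_r: float = 398.0,
    lambda_ex: np.ndarray = EXTENDED_GRID,
    seed: int = 0,
) -> dict:
    """Coverage of the shared relaxed baseline's 95% CI in joint fits.

    Each experiment simulates ``n_curves`` curves sharing ``csm_r`` but with
    distinct Franck-Condon baselines, gradients and midpoints, fits them
    jointly, and checks whether the normal-approximation 95% CI of the
    shared estimate covers the truth.  Uses the extended excitation grid,
    where saturation makes the shared baseline identifiable.
    """
    rng = np.random.default_rng(seed)
    fcs = np.linspace(352.0, 364.0, n_curves)
    ms = np.linspace(250.0, 450.0, n_curves)
    mids = np.linspace(310.0, 320.0, n_curves)
    covered, estimates = 0, []
    for _ in range(n_experiments):
        curves = [
            generate_csm_curve(
                ThermoParams(csm_fc=fc, csm_r=csm_r, m=m, lambda50=mid),
                lambda_ex,
                noise_sd,
                rng,
            )
            for fc, m, mid in zip(fcs, ms, mids)
        ]
        res = GlobalREESModel(curves).fit()
        estimates.append(res.csm_r)
        ci = res.conf_int_csm_r()
        if ci is not None and ci[0] <= csm_r <= ci[1]:
            covered += 1
    return {
        "n": n_experiments,
        "coverage": covered / n_experiments,
        "mean_estimate": float(np.mean(estimates)),
        "truth": csm_r,
    }


def csm_r_sensitivity_study(
    csm_r_grid: np.ndarray | None = None,
    truth: ThermoParams = PROTEIN_TRUTH,
    lambda_ex: np.ndarray = ACCESSIBLE_GRID,
) -> dict:
    """Effect of the fixed relaxed baseline on the extracted m and CSM_FC.

    Refits one noiseless synthetic curve with ``csm_r`` pinned across the
    plausible 387-440 nm range; reports the spread of m relative to its
    value at the true baseline, the maximum change in CSM_FC, and the
    maximum step between adjacent grid points (smoothness).

    Defaults to the protein-like truth: when the transition midpoint lies
    near the accessible window (solution-tryptophan-like curves) the
    Franck-Condon baseline does couple to the assumed relaxed baseline,
    which this study would expose.
    """
    grid = (
        np.arange(387.0, 441.0, 2.0) if csm_r_grid is None else np.asarray(csm_r_grid)
    )
    curve = generate_csm_curve(truth, lambda_ex, noise_sd=0.0)
    m_vals, fc_vals = [], []
    for fixed in grid:
        res = REESModel(curve, fix_csm_r=float(fixed)).fit()
        m_vals.append(res.params.m)
        fc_vals.append(res.params.csm_fc)
    m_vals = np.asarray(m_vals)
    fc_vals = np.asarray(fc_vals)
    m_ref = REESModel(curve, fix_csm_r=truth.csm_r).fit().params.m
    return {
        "n": grid.size,
        "csm_r_grid": grid,
        "m_values": m_vals,
        "csm_fc_values": fc_vals,
        "max_rel_dev_m": float(np.max(np.abs(m_vals - m_ref)) / m_ref),
        "max_abs_dev_csm_fc": float(np.max(np.abs(fc_vals - truth.csm_fc))),
        "max_step_rel_m": float(np.max(np.abs(np.diff(m_vals))) / m_ref),
    }


MELT_TRUTH = {"tm": 330.0, "dh": 300e3, "b_f": -20.0, "a_f": 0.02,
              "b_u": -2.0, "a_u": 0.002}


def melt_recovery_study(
    n_curves: int = 100,
    noise_frac: float = 0.01,
    truth: dict | None = None,
    temperatures: np.ndarray | None = None,
    seed: int = 0,
) -> dict:
    """Recovery of Tm and the van't Hoff enthalpy from noisy melts.

    Noise is ``noise_frac`` of the folded-to-unfolded signal span (1% by
    default, typical of CD ellipticity traces).
    """
    truth = dict(MELT_TRUTH if truth is None else truth)
    t = np.arange(288.0, 372.0) if temperatures is None else temperatures
    clean, _ = generate_melt_curve(temperatures=t, noise_sd=0.0, **truth)
    span = float(clean.ellipticity_222.max() - clean.ellipticity_222.min())
    rng = np.random.default_rng(seed)
    err_tm, err_dh = [], []
    for _ in range(n_curves):
        curve, _ = generate_melt_curve(
            temperatures=t, noise_sd=noise_frac * span, seed=rng, **truth
        )
        res = MeltModel(curve).fit()
        err_tm.append(abs(res.tm - truth["tm"]))
        err_dh.append(abs(res.dh - truth["dh"]) / truth["dh"])
    return {
        "n": n_curves,
        "median_abs_err_tm": float(np.median(err_tm)),
        "median_rel_err_dh": float(np.median(err_dh)),
    }


def melt_truncation_study(
    tm: float = 378.65,  # 105.5 C: transition above the measurable range
    dh: float = 250e3,
    noise_frac: float = 0.01,
    seed: int = 0,
) -> dict:
    """Restrained fit of a melt truncated below its transition midpoint.

    Emulates a hyperthermophile melt measured only to ~95 C: the unfolded
    limb is pinned to zero and the fitted Tm extrapolates beyond the data,
    which the results flag.
    """
    t = np.arange(293.0, 369.0)  # 20-95 C
    truth = {"tm": tm, "dh": dh, "b_f": -20.0, "a_f": 0.05, "b_u": 0.0, "a_u": 0.0}
    clean, _ = generate_melt_curve(temperatures=t, noise_sd=0.0, **truth)
    span = float(clean.ellipticity_222.max() - clean.ellipticity_222.min())
    curve, _ = generate_melt_curve(
        temperatures=t, noise_sd=noise_frac * span, seed=seed, **truth
    )
    res = MeltModel(curve, restrain_unfolded_to_zero=True).fit()
    return {
        "n": t.size,
        "tm_estimate": res.tm,
        "tm_truth": tm,
        "t_max": float(t[-1]),
        "extrapolated": res.extrapolated,
    }


def breakpoint_recovery_study(
    n_runs: int = 100,
    break_celsius: float = 55.0,
    slope_low: float = -0.1e-3,  # J mol^-1 nm^-1 K^-1
    slope_high: float = -0.25e-3,
    m_at_start: float = 0.010,
    noise_sd: float = 1e-4,
    seed: int = 0,
) -> dict:
    """Recovery of a breakpoint in the temperature dependence of m.

    m declines linearly with temperature, steepening at the breakpoint (the
    signature of an unfolding onset); temperatures span 15-75 C in 5 C
    steps.  Success means the fitted breakpoint lands within one step of
    the truth.
    """
    t = np.arange(15.0, 76.0, 5.0) + CELSIUS_OFFSET
    tb = break_celsius + CELSIUS_OFFSET
    clean = m_at_start + slope_low * (t - t[0])
    above = t > tb
    clean[above] = (
        m_at_start + slope_low * (tb - t[0]) + slope_high * (t[above] - tb)
    )
    rng = np.random.default_rng(seed)
    hits, breakpoints = 0, []
    step = float(t[1] - t[0])
    for _ in range(n_runs):
        y = clean + rng.normal(0.0, noise_sd, t.size)
        trend = temperature_trend(list(zip(t, y)), allow_breakpoint=True)
        if trend.has_breakpoint:
            breakpoints.append(trend.breakpoint)
            if abs(trend.breakpoint - tb) <= step:
                hits += 1
    return {
        "n": n_runs,
        "success_rate": hits / n_runs,
        "breakpoint_truth": tb,
        "step": step,
        "n_detected": len(breakpoints),
    }
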