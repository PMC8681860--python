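"""Model/Results classes for fitting CSM curves.

The surface follows the statsmodels idiom: a model object is built from
data, ``fit()`` returns a results object carrying estimates, standard
errors, diagnostics and a ``summary()`` table.

* :class:`REESModel` — fit one CSM curve with the two-state photoselection
  sigmoid, optionally holding the relaxed-state baseline ``csm_r`` fixed
  (the practical choice when only the experimentally accessible excitation
  window, up to ~310 nm, was measured).
* :class:`GlobalREESModel` — joint fit of several curves with ``csm_r``
  shared, the restraint that makes the relaxed-state baseline identifiable
  from truncated data.
* :class:`QubesModel` — the legacy empirical exponential.
* :func:`delta_delta_g` — compare the flexibility statistic m between two
  fits.
* :func:`temperature_trend` — linear or broken-line regression of m versus
  temperature, the analysis that localises unfolding onsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import stats

from .csm import CSMCurve
from .exceptions import ConvergenceError, ValidationError
from .models import (
    GAS_CONSTANT,
    QubesParams,
    ThermoParams,
    delta_g_at,
    qubes_csm,
    resolve_temperature,
    thermo_csm,
)

DEFAULT_CSM_R = 398.7  # nm; relaxed-state baseline of tryptophan in solution
PROTEIN_CSM_R = 395.4  # nm; limiting value pooled across solution + protein data
CSM_R_CEILING = 1000.0  # nm; unconstrained fits beyond this are unphysical


def _curve_weights(curve: CSMCurve) -> np.ndarray | None:
    err = curve.csm_errors
    if err is None or np.any(err <= 0):
        return None
    return 1.0 / err


# ---------------------------------------------------------------------------
# two-state photoselection fit
# ---------------------------------------------------------------------------


class REESModel:
    """Two-state photoselection model for one CSM curve.

    Parameters
    ----------
    curve : CSMCurve
        The (excitation wavelength, CSM) data; ``csm_errors``, when present
        and positive, are used as inverse weights.
    fix_csm_r : float, optional
        Hold the relaxed-state baseline at this value (nm) instead of
        estimating it; 398.7 nm (solution tryptophan) and 395.4 nm (pooled
        protein) are the standard choices.
    literal_form : bool
        Use the unweighted-FC variant of the sigmoid (comparison only).
    temperature : float, optional
        Kelvin; defaults to the curve's own temperature, falling back to
        298.15 K with a warning.
    """

    def __init__(
        self,
        curve: CSMCurve,
        fix_csm_r: float | None = None,
        literal_form: bool = False,
        temperature: float | None = None,
        gas_constant: float = GAS_CONSTANT,
        csm_r_ceiling: float = CSM_R_CEILING,
    ):
        if len(curve) < 5:
            raise ValidationError(
                f"two-state fit needs >= 5 points, got {len(curve)}"
            )
        self.curve = curve
        self.fix_csm_r = None if fix_csm_r is None else float(fix_csm_r)
        self.literal_form = bool(literal_form)
        self.temperature = resolve_temperature(
            temperature if temperature is not None else curve.temperature
        )
        self.gas_constant = float(gas_constant)
        self.csm_r_ceiling = float(csm_r_ceiling)
        self._lam = curve.excitation_wavelengths
        self._y = curve.csm_values
        self._w = _curve_weights(curve)

    @classmethod
    def from_dataframe(cls, df, temperature: float | None = None, **kwargs) -> "REESModel":
        return cls(CSMCurve.from_dataframe(df), temperature=temperature, **kwargs)

    # -- parameter setup ----------------------------------------------------

    def _bounds_csm_fc(self) -> tuple[float, float]:
        if self.curve.emission_window is not None:
            return self.curve.emission_window
        y = self._y
        return float(y.min() - 50.0), float(y.max() + 10.0)

    def _start_values(self) -> dict:
        lam, y = self._lam, self._y
        span = float(lam[-1] - lam[0])
        rt = self.gas_constant * self.temperature
        return {
            "csm_fc": float(y.min()),
            "csm_r": DEFAULT_CSM_R if self.fix_csm_r is None else self.fix_csm_r,
            "lambda50": float(lam[-1] + 10.0),
            # start with the logistic argument spanning ~2 units across the window
            "m": 2.0 * rt / span,
        }

    def _make_params(self, start: dict) -> lmfit.Parameters:
        lam = self._lam
        fc_lo, fc_hi = self._bounds_csm_fc()
        p = lmfit.Parameters()
        p.add("csm_fc", value=np.clip(start["csm_fc"], fc_lo, fc_hi), min=fc_lo, max=fc_hi)
        if self.fix_csm_r is None:
            p.add(
                "csm_r",
                value=np.clip(start["csm_r"], fc_lo, self.csm_r_ceiling),
                min=fc_lo,
                max=self.csm_r_ceiling,
            )
        else:
            p.add("csm_r", value=self.fix_csm_r, vary=False)
        p.add("m", value=max(start["m"], 1e-9), min=1e-9, max=1e7)
        p.add(
            "lambda50",
            value=np.clip(start["lambda50"], lam[0], lam[0] + 200.0),
            min=float(lam[0]),
            max=float(lam[0] + 200.0),
        )
        return p

    def _predict(self, values: dict, lam: np.ndarray) -> np.ndarray:
        params = ThermoParams(
            csm_fc=values["csm_fc"],
            csm_r=max(values["csm_r"], values["csm_fc"]),
            m=values["m"],
            lambda50=values["lambda50"],
            temperature=self.temperature,
            gas_constant=self.gas_constant,
        )
        return np.asarray(thermo_csm(params, lam, literal_form=self.literal_form))

    def _residual(self, params: lmfit.Parameters) -> np.ndarray:
        v = params.valuesdict()
        resid = self._predict(v, self._lam) - self._y
        return resid if self._w is None else resid * self._w

    def _jittered_starts(self, n_starts: int, seed: int) -> list[dict]:
        base = self._start_values()
        starts = [base]
        rng = np.random.default_rng(seed)
        for _ in range(max(0, n_starts - 1)):
            s = dict(base)
            s["csm_fc"] = base["csm_fc"] + rng.normal(0, 2.0)
            s["lambda50"] = base["lambda50"] + rng.normal(0, 5.0)
            s["m"] = base["m"] * float(np.exp(rng.normal(0, 0.3)))
            if self.fix_csm_r is None:
                s["csm_r"] = base["csm_r"] + rng.normal(0, 10.0)
            starts.append(s)
        return starts

    # -- fitting ------------------------------------------------------------

    def fit(
        self, n_starts: int = 5, seed: int = 0, bootstrap: int | None = None
    ) -> "REESResults":
        """Bounded nonlinear least squares with multi-start initialisation.

        ``n_starts`` jittered initialisations (seeded) guard against local
        minima; the lowest-SSE converged solution is returned.  With
        ``bootstrap`` set (e.g. 200), standard errors come from a seeded
        residual bootstrap instead of the Jacobian covariance — more honest
        for short curves where the quadratic approximation is poor.
        """
        best, n_ok = None, 0
        starts = self._jittered_starts(n_starts, seed)
        for start in starts:
            try:
                res = lmfit.minimize(
                    self._residual, self._make_params(start), method="least_squares"
                )
            except Exception:
                continue
            if not res.success:
                continue
            n_ok += 1
            if best is None or res.chisqr < best.chisqr:
                best = res
        if best is None:
            raise ConvergenceError(
                "two-state fit failed to converge from every start",
                initial_values=starts[0],
            )
        out = self._package(best, n_ok, n_starts)
        if bootstrap:
            out.bse = self._bootstrap_errors(out, n_resamples=bootstrap, seed=seed)
        return out

    def _bootstrap_errors(
        self, result: "REESResults", n_resamples: int = 200, seed: int = 0
    ) -> dict:
        """Residual-bootstrap standard errors around a converged fit."""
        rng = np.random.default_rng(seed + 1)
        fitted = np.asarray(result.predict(self._lam))
        resid = self._y - fitted
        start = {
            "csm_fc": result.params.csm_fc,
            "csm_r": result.params.csm_r,
            "m": result.params.m,
            "lambda50": result.params.lambda50,
        }
        draws: dict[str, list] = {k: [] for k in ("csm_fc", "csm_r", "m", "lambda50")}
        y_orig = self._y
        try:
            for _ in range(n_resamples):
                self._y = fitted + rng.choice(resid, size=resid.size, replace=True)
                try:
                    res = lmfit.minimize(
                        self._residual, self._make_params(start), method="least_squares"
                    )
                except Exception:
                    continue
                if not res.success:
                    continue
                for k in draws:
                    draws[k].append(res.params[k].value)
        finally:
            self._y = y_orig
        varied = {"csm_fc", "m", "lambda50"}
        if self.fix_csm_r is None:
            varied.add("csm_r")
        bse = dict(result.bse)
        for k, values in draws.items():
            if k in varied and len(values) >= 10:
                bse[k] = float(np.std(values, ddof=1))
        return bse

    def _package(self, res, n_ok: int, n_starts: int) -> "REESResults":
        v = res.params.valuesdict()
        params = ThermoParams(
            csm_fc=v["csm_fc"],
            csm_r=max(v["csm_r"], v["csm_fc"]),
            m=v["m"],
            lambda50=v["lambda50"],
            temperature=self.temperature,
            gas_constant=self.gas_constant,
        )
        bse = {}
        fixed = {"csm_r": self.fix_csm_r is not None}
        for name in ("csm_fc", "csm_r", "m", "lambda50"):
            par = res.params[name]
            bse[name] = float(par.stderr) if (par.vary and par.stderr is not None) else None
        resid = self._predict(v, self._lam) - self._y
        implausible = (
            self.fix_csm_r is None and params.csm_r >= 0.999 * self.csm_r_ceiling
        )
        return REESResults(
            params=params,
            bse=bse,
            fixed=fixed,
            rms=float(np.sqrt(np.mean(resid**2))),
            n_points=len(self.curve),
            n_starts_converged=n_ok,
            n_starts=n_starts,
            success=True,
            csm_r_implausible=bool(implausible),
            literal_form=self.literal_form,
            model=self,
        )


@dataclass
class REESResults:
    """Estimates and diagnostics from a two-state photoselection fit.

    ``params.m`` — the gradient of the free-energy gap versus excitation
    wavelength, in J mol^-1 nm^-1 — is the headline flexibility statistic.
    """

    params: ThermoParams
    bse: dict
    fixed: dict
    rms: float
    n_points: int
    n_starts_converged: int
    n_starts: int
    success: bool
    csm_r_implausible: bool = False
    literal_form: bool = False
    shared: tuple = ()
    model: object = field(default=None, repr=False)

    @property
    def m(self) -> float:
        return self.params.m

    def predict(self, lambda_ex) -> np.ndarray:
        return thermo_csm(self.params, lambda_ex, literal_form=self.literal_form)

    def delta_g(self, lambda_ex):
        """Free-energy gap (J mol^-1) at an excitation wavelength."""
        return delta_g_at(self.params, lambda_ex)

    def conf_int(self, name: str, alpha: float = 0.05) -> tuple[float, float] | None:
        """Normal-approximation confidence interval for one parameter."""
        se = self.bse.get(name)
        if se is None:
            return None
        value = getattr(self.params, name)
        z = stats.norm.ppf(1 - alpha / 2)
        return (value - z * se, value + z * se)

    def overlay_dataframe(self):
        """(lambda_ex, observed CSM, fitted CSM) table for export/plotting."""
        import pandas as pd

        curve = self.model.curve
        return pd.DataFrame(
            {
                "excitation_wavelength": curve.excitation_wavelengths,
                "csm_obs": curve.csm_values,
                "csm_fit": self.predict(curve.excitation_wavelengths),
            }
        )

    def summary(self) -> str:
        lines = [
            "Two-state photoselection fit (CSM vs excitation wavelength)",
            f"  points: {self.n_points}   residual RMS: {self.rms:.4g} nm   "
            f"starts converged: {self.n_starts_converged}/{self.n_starts}",
            f"  temperature: {self.params.temperature:.2f} K",
            f"  {'parameter':<10} {'value':>12} {'std err':>12}  note",
        ]
        notes = {
            "csm_fc": "Franck-Condon baseline (nm)",
            "csm_r": "relaxed baseline (nm)",
            "m": "dG gradient (J mol^-1 nm^-1)",
            "lambda50": "transition midpoint (nm)",
        }
        for name in ("csm_fc", "csm_r", "m", "lambda50"):
            value = getattr(self.params, name)
            se = self.bse.get(name)
            tag = notes[name]
            if name in self.shared:
                tag += " [shared]"
            elif self.fixed.get(name):
                tag += " [fixed]"
            se_txt = f"{se:12.5g}" if se is not None else f"{'--':>12}"
            lines.append(f"  {name:<10} {value:12.6g} {se_txt}  {tag}")
        if self.csm_r_implausible:
            lines.append(
                "  warning: unconstrained csm_r at its plausibility ceiling; "
                "fix or share csm_r instead"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay the fitted sigmoid on the observed CSM curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.model.curve
        lam = curve.excitation_wavelengths
        ax.errorbar(lam, curve.csm_values, yerr=curve.csm_errors, fmt="o", label="CSM")
        grid = np.linspace(lam[0], lam[-1], 200)
        ax.plot(grid, self.predict(grid), "-", label="two-state fit")
        ax.set_xlabel("excitation wavelength (nm)")
        ax.set_ylabel("CSM (nm)")
        ax.legend()
        return ax


def fit_thermo(
    curve: CSMCurve,
    fix_csm_r: float | None = None,
    temperature: float | None = None,
    n_starts: int = 5,
    seed: int = 0,
    **kwargs,
) -> REESResults:
    """Functional wrapper: build a :class:`REESModel` and fit it."""
    return REESModel(
        curve, fix_csm_r=fix_csm_r, temperature=temperature, **kwargs
    ).fit(n_starts=n_starts, seed=seed)


# ---------------------------------------------------------------------------
# global (shared csm_r) fit
# ---------------------------------------------------------------------------


@dataclass
class GlobalREESResults:
    """Joint-fit results: one shared relaxed baseline plus per-curve fits."""

    csm_r: float
    csm_r_stderr: float | None
    results: list[REESResults]
    rms: float
    n_points: int

    def conf_int_csm_r(self, alpha: float = 0.05) -> tuple[float, float] | None:
        if self.csm_r_stderr is None:
            return None
        z = stats.norm.ppf(1 - alpha / 2)
        return (self.csm_r - z * self.csm_r_stderr, self.csm_r + z * self.csm_r_stderr)

    def summary(self) -> str:
        se = f"{self.csm_r_stderr:.4g}" if self.csm_r_stderr is not None else "--"
        lines = [
            "Global two-state fit with shared relaxed baseline",
            f"  curves: {len(self.results)}   points: {self.n_points}   "
            f"residual RMS: {self.rms:.4g} nm",
            f"  shared csm_r: {self.csm_r:.4f} +/- {se} nm",
        ]
        for i, r in enumerate(self.results):
            cond = r.model.curve.condition if r.model is not None else ""
            lines.append(f"  --- curve {i} {cond}")
            lines.extend("  " + ln for ln in r.summary().splitlines()[1:])
        return "\n".join(lines)


class GlobalREESModel:
    """Joint two-state fit of several CSM curves with one shared ``csm_r``.

    Each curve keeps its own Franck-Condon baseline, gradient m and midpoint;
    stacking the residuals under a single relaxed baseline is what makes
    ``csm_r`` identifiable when no single curve reaches saturation.  Curves
    need not share excitation grids.  With a single curve this reduces
    exactly to :class:`REESModel`.
    """

    def __init__(
        self,
        curves: list[CSMCurve],
        temperatures: list[float] | None = None,
        literal_form: bool = False,
        gas_constant: float = GAS_CONSTANT,
        csm_r_ceiling: float = CSM_R_CEILING,
    ):
        if len(curves) < 1:
            raise ValidationError("global fit needs at least one curve")
        if temperatures is not None and len(temperatures) != len(curves):
            raise ValidationError("one temperature per curve required")
        self.curves = list(curves)
        self.temperatures = [
            resolve_temperature(
                temperatures[i] if temperatures is not None else c.temperature
            )
            for i, c in enumerate(curves)
        ]
        for c in curves:
            if len(c) < 5:
                raise ValidationError("every curve needs >= 5 points")
        self.literal_form = bool(literal_form)
        self.gas_constant = float(gas_constant)
        self.csm_r_ceiling = float(csm_r_ceiling)
        self._members = [
            REESModel(
                c,
                literal_form=literal_form,
                temperature=self.temperatures[i],
                gas_constant=gas_constant,
                csm_r_ceiling=csm_r_ceiling,
            )
            for i, c in enumerate(curves)
        ]

    def _residual(self, params: lmfit.Parameters) -> np.ndarray:
        v = params.valuesdict()
        chunks = []
        for i, member in enumerate(self._members):
            values = {
                "csm_fc": v[f"csm_fc_{i}"],
                "csm_r": v["csm_r"],
                "m": v[f"m_{i}"],
                "lambda50": v[f"lambda50_{i}"],
            }
            resid = member._predict(values, member._lam) - member._y
            chunks.append(resid if member._w is None else resid * member._w)
        return np.concatenate(chunks)

    def fit(self, n_starts: int = 5, seed: int = 0) -> GlobalREESResults:
        if len(self._members) == 1:
            single = self._members[0].fit(n_starts=n_starts, seed=seed)
            single.shared = ("csm_r",)
            return GlobalREESResults(
                csm_r=single.params.csm_r,
                csm_r_stderr=single.bse.get("csm_r"),
                results=[single],
                rms=single.rms,
                n_points=single.n_points,
            )

        rng = np.random.default_rng(seed)
        best, n_ok = None, 0
        for k in range(n_starts):
            p = lmfit.Parameters()
            lo = min(m._bounds_csm_fc()[0] for m in self._members)
            csm_r0 = DEFAULT_CSM_R + (rng.normal(0, 10.0) if k else 0.0)
            p.add("csm_r", value=np.clip(csm_r0, lo, self.csm_r_ceiling),
                  min=lo, max=self.csm_r_ceiling)
            for i, member in enumerate(self._members):
                base = member._start_values()
                if k:
                    base["csm_fc"] += rng.normal(0, 2.0)
                    base["lambda50"] += rng.normal(0, 5.0)
                    base["m"] *= float(np.exp(rng.normal(0, 0.3)))
                sub = member._make_params(base)
                fc_lo, fc_hi = member._bounds_csm_fc()
                p.add(f"csm_fc_{i}", value=sub["csm_fc"].value, min=fc_lo, max=fc_hi)
                p.add(f"m_{i}", value=sub["m"].value, min=1e-9, max=1e7)
                p.add(
                    f"lambda50_{i}",
                    value=sub["lambda50"].value,
                    min=sub["lambda50"].min,
                    max=sub["lambda50"].max,
                )
            try:
                res = lmfit.minimize(self._residual, p, method="least_squares")
            except Exception:
                continue
            if not res.success:
                continue
            n_ok += 1
            if best is None or res.chisqr < best.chisqr:
                best = res
        if best is None:
            raise ConvergenceError("global two-state fit failed to converge")
        return self._package(best, n_ok, n_starts)

    def _package(self, res, n_ok: int, n_starts: int) -> GlobalREESResults:
        v = res.params.valuesdict()
        shared_se = res.params["csm_r"].stderr
        shared_se = float(shared_se) if shared_se is not None else None
        results = []
        total_sq = 0
        n_total = 0
        for i, member in enumerate(self._members):
            params = ThermoParams(
                csm_fc=v[f"csm_fc_{i}"],
                csm_r=max(v["csm_r"], v[f"csm_fc_{i}"]),
                m=v[f"m_{i}"],
                lambda50=v[f"lambda50_{i}"],
                temperature=member.temperature,
                gas_constant=member.gas_constant,
            )
            bse = {"csm_r": shared_se}
            for short, name in (
                ("csm_fc", f"csm_fc_{i}"),
                ("m", f"m_{i}"),
                ("lambda50", f"lambda50_{i}"),
            ):
                se = res.params[name].stderr
                bse[short] = float(se) if se is not None else None
            resid = member._predict(
                {
                    "csm_fc": params.csm_fc,
                    "csm_r": v["csm_r"],
                    "m": params.m,
                    "lambda50": params.lambda50,
                },
                member._lam,
            ) - member._y
            total_sq += float(np.sum(resid**2))
            n_total += resid.size
            results.append(
                REESResults(
                    params=params,
                    bse=bse,
                    fixed={"csm_r": False},
                    rms=float(np.sqrt(np.mean(resid**2))),
                    n_points=len(member.curve),
                    n_starts_converged=n_ok,
                    n_starts=n_starts,
                    success=True,
                    csm_r_implausible=v["csm_r"] >= 0.999 * self.csm_r_ceiling,
                    literal_form=self.literal_form,
                    shared=("csm_r",),
                    model=member,
                )
            )
        return GlobalREESResults(
            csm_r=float(v["csm_r"]),
            csm_r_stderr=shared_se,
            results=results,
            rms=float(np.sqrt(total_sq / n_total)),
            n_points=n_total,
        )


def fit_thermo_global(
    curves: list[CSMCurve], n_starts: int = 5, seed: int = 0, **kwargs
) -> GlobalREESResults:
    """Functional wrapper: build a :class:`GlobalREESModel` and fit it."""
    return GlobalREESModel(curves, **kwargs).fit(n_starts=n_starts, seed=seed)


# ---------------------------------------------------------------------------
# empirical exponential (QUBES) fit
# ---------------------------------------------------------------------------


@dataclass
class QubesResults:
    params: QubesParams
    bse: dict
    rms: float
    n_points: int
    success: bool
    model: object = field(default=None, repr=False)

    def predict(self, lambda_ex):
        return qubes_csm(self.params, lambda_ex)

    def summary(self) -> str:
        lines = [
            "Empirical exponential (QUBES) fit",
            f"  points: {self.n_points}   residual RMS: {self.rms:.4g} nm",
            f"  reference wavelength: {self.params.reference_lambda} nm",
        ]
        for name in ("csm0", "amplitude", "curvature"):
            se = self.bse.get(name)
            se_txt = f"{se:.4g}" if se is not None else "--"
            lines.append(f"  {name:<10} {getattr(self.params, name):12.6g} +/- {se_txt}")
        return "\n".join(lines)


class QubesModel:
    """Empirical exponential description of a CSM curve.

    ``CSM = CSM0 + A * exp(Rc * (lam_ex - lam_ref))`` with the reference
    wavelength anchored at the curve's lowest excitation wavelength.  Kept
    for continuity with earlier red-edge analyses; it has no saturation, so
    extrapolation beyond the measured window is meaningless.
    """

    def __init__(self, curve: CSMCurve):
        if len(curve) < 4:
            raise ValidationError(f"QUBES fit needs >= 4 points, got {len(curve)}")
        self.curve = curve
        self._lam = curve.excitation_wavelengths
        self._y = curve.csm_values
        self._w = _curve_weights(curve)
        self.reference_lambda = float(self._lam[0])

    def _residual(self, params: lmfit.Parameters) -> np.ndarray:
        v = params.valuesdict()
        model = v["csm0"] + v["amplitude"] * np.exp(
            np.clip(v["curvature"] * (self._lam - self.reference_lambda), -700, 700)
        )
        resid = model - self._y
        return resid if self._w is None else resid * self._w

    def fit(self, n_starts: int = 5, seed: int = 0) -> QubesResults:
        y = self._y
        span = float(self._lam[-1] - self._lam[0])
        base_curv = 2.0 / span
        rng = np.random.default_rng(seed)
        starts = [
            {"csm0": float(y[0]), "amplitude": max(float(y[-1] - y[0]), 1e-3),
             "curvature": c}
            for c in (base_curv, 0.5 * base_curv, 2.0 * base_curv)
        ]
        while len(starts) < n_starts:
            starts.append(
                {
                    "csm0": float(y[0] + rng.normal(0, 1.0)),
                    "amplitude": max(float(y[-1] - y[0]), 1e-3)
                    * float(np.exp(rng.normal(0, 0.5))),
                    "curvature": base_curv * float(np.exp(rng.normal(0, 0.7))),
                }
            )
        best, n_ok = None, 0
        for s in starts[:n_starts] if n_starts >= 3 else starts[:max(n_starts, 1)]:
            p = lmfit.Parameters()
            p.add("csm0", value=s["csm0"], min=y.min() - 100.0, max=y.max() + 100.0)
            p.add("amplitude", value=s["amplitude"], min=0.0, max=1e4)
            p.add("curvature", value=s["curvature"], min=1e-6, max=5.0)
            try:
                res = lmfit.minimize(self._residual, p, method="least_squares")
            except Exception:
                continue
            if not res.success:
                continue
            n_ok += 1
            if best is None or res.chisqr < best.chisqr:
                best = res
        if best is None:
            raise ConvergenceError(
                "QUBES fit failed to converge", initial_values=starts[0]
            )
        v = best.params.valuesdict()
        params = QubesParams(
            csm0=v["csm0"],
            amplitude=v["amplitude"],
            curvature=v["curvature"],
            reference_lambda=self.reference_lambda,
        )
        bse = {
            name: (float(best.params[name].stderr)
                   if best.params[name].stderr is not None else None)
            for name in ("csm0", "amplitude", "curvature")
        }
        resid = qubes_csm(params, self._lam) - y
        return QubesResults(
            params=params,
            bse=bse,
            rms=float(np.sqrt(np.mean(np.asarray(resid) ** 2))),
            n_points=len(self.curve),
            success=True,
            model=self,
        )


def fit_qubes(curve: CSMCurve, n_starts: int = 5, seed: int = 0) -> QubesResults:
    return QubesModel(curve).fit(n_starts=n_starts, seed=seed)


# ---------------------------------------------------------------------------
# comparisons and trends
# ---------------------------------------------------------------------------


def delta_delta_g(a: REESResults, b: REESResults) -> tuple[float, float]:
    """Difference in the flexibility statistic, ``m_a - m_b`` (J mol^-1 nm^-1).

    The uncertainty is propagated in quadrature assuming independent fits;
    it is NaN when either fit lacks a standard error for m.
    """
    ddg = a.params.m - b.params.m
    sa, sb = a.bse.get("m"), b.bse.get("m")
    err = float(np.hypot(sa, sb)) if (sa is not None and sb is not None) else float("nan")
    return float(ddg), err


@dataclass
class TrendResult:
    """Linear (optionally broken-line) trend of m versus temperature."""

    temperatures: np.ndarray
    m_values: np.ndarray
    slope: float  # single-line slope, J mol^-1 nm^-1 K^-1
    slope_stderr: float
    intercept: float
    sse_linear: float
    breakpoint: float | None = None  # K
    slopes: tuple[float, float] | None = None  # (below, above breakpoint)
    slope_stderrs: tuple[float, float] | None = None
    intercepts: tuple[float, float] | None = None
    sse_breakpoint: float | None = None
    p_value: float | None = None
    alpha: float | None = None

    @property
    def has_breakpoint(self) -> bool:
        return self.breakpoint is not None

    def summary(self) -> str:
        lines = [
            "Temperature trend of the flexibility statistic m",
            f"  n: {self.temperatures.size}   "
            f"linear slope: {self.slope:.4g} +/- {self.slope_stderr:.4g} J mol^-1 nm^-1 K^-1",
        ]
        if self.has_breakpoint:
            lines.append(
                f"  breakpoint: {self.breakpoint:.2f} K "
                f"(p = {self.p_value:.3g} vs single line)"
            )
            lines.append(
                f"  segment slopes: {self.slopes[0]:.4g} (below), "
                f"{self.slopes[1]:.4g} (above)"
            )
        elif self.p_value is not None:
            lines.append(
                f"  no significant breakpoint (best p = {self.p_value:.3g}, "
                f"alpha = {self.alpha})"
            )
        return "\n".join(lines)


def _extract_m(entry) -> float:
    if isinstance(entry, REESResults):
        return entry.params.m
    return float(entry)


def temperature_trend(
    results,
    allow_breakpoint: bool = False,
    alpha: float = 0.05,
) -> TrendResult:
    """Regress the flexibility statistic m on temperature.

    Parameters
    ----------
    results : sequence of (temperature_K, m) pairs
        ``m`` may be a float or a :class:`REESResults`.
    allow_breakpoint : bool
        Also fit a continuous two-segment broken line, searching the
        breakpoint over the interior observed temperatures, and report it
        only when an F-test prefers it to the single line at level ``alpha``.
    """
    pairs = [(float(t), _extract_m(m)) for t, m in results]
    pairs.sort(key=lambda p: p[0])
    t = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    n = t.size
    if n < 3:
        raise ValidationError("trend needs >= 3 temperatures")
    if allow_breakpoint and n < 5:
        raise ValidationError("breakpoint search needs >= 5 temperatures")

    lin = stats.linregress(t, y)
    sse0 = float(np.sum((y - (lin.intercept + lin.slope * t)) ** 2))
    out = TrendResult(
        temperatures=t,
        m_values=y,
        slope=float(lin.slope),
        slope_stderr=float(lin.stderr),
        intercept=float(lin.intercept),
        sse_linear=sse0,
    )
    if not allow_breakpoint:
        return out

    out.alpha = alpha
    scale = max(float(np.sum(y**2)), 1.0)
    if sse0 <= 1e-18 * scale:  # the single line is already exact
        out.p_value = 1.0
        return out

    best = None
    for tb in t[1:-1]:
        X = np.column_stack([np.ones(n), t, np.maximum(t - tb, 0.0)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((y - X @ beta) ** 2))
        if best is None or sse < best[0]:
            best = (sse, float(tb), beta, X)
    sse1, tb, beta, X = best
    dof = n - 4  # intercept, base slope, slope change, searched breakpoint
    if dof <= 0:
        raise ValidationError("too few points for the breakpoint model")
    if sse1 <= 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = ((sse0 - sse1) / 2.0) / (sse1 / dof)
        p = float(stats.f.sf(f_stat, 2, dof))
    out.p_value = p
    if p < alpha:
        xtx_inv = np.linalg.inv(X.T @ X)
        cov = (sse1 / dof if sse1 > 0 else 0.0) * xtx_inv
        se_low = float(np.sqrt(max(cov[1, 1], 0.0)))
        se_high = float(np.sqrt(max(cov[1, 1] + cov[2, 2] + 2 * cov[1, 2], 0.0)))
        out.breakpoint = tb
        out.slopes = (float(beta[1]), float(beta[1] + beta[2]))
        out.slope_stderrs = (se_low, se_high)
        out.intercepts = (float(beta[0]), float(beta[0] - beta[2] * tb))
        out.sse_breakpoint = sse1
    return out
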