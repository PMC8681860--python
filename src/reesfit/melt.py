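"""Two-state van't Hoff fitting of CD thermal melts.

The ellipticity at 222 nm is modelled as a population-weighted mix of two
linear baselines,

    signal(T) = [(b_f + a_f T) + (b_u + a_u T) Ku] / (1 + Ku),
    Ku(T)     = exp(-dH (1 - T/Tm) / (R T)),

with melting temperature Tm (K) and van't Hoff enthalpy of unfolding dH
(J mol^-1); Ku(Tm) = 1, so the transition midpoint sits halfway between
the baselines, and the unfolded limb dominates above Tm.

For very stable proteins whose transition lies above the experimentally
accessible range, the unfolded limb is unobserved and the unrestrained fit
is degenerate; the standard remedy is to pin the unfolded baseline's
intercept and gradient to zero (``restrain_unfolded_to_zero=True``) and
accept an extrapolated Tm, which the results flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .exceptions import ConvergenceError, NonIdentifiableError, ValidationError
from .io import MeltCurve, kelvin_to_celsius
from .models import GAS_CONSTANT, melt_signal


@dataclass
class MeltResults:
    """Estimates from a two-state melt fit."""

    tm: float  # K
    dh: float  # J mol^-1
    b_f: float
    a_f: float
    b_u: float
    a_u: float
    bse: dict
    restrained: bool
    extrapolated: bool
    rms: float
    n_points: int
    literal_form: bool = False
    gas_constant: float = GAS_CONSTANT
    model: object = field(default=None, repr=False)

    @property
    def tm_celsius(self) -> float:
        return kelvin_to_celsius(self.tm)

    def predict(self, temperature):
        return melt_signal(
            temperature,
            self.tm,
            self.dh,
            self.b_f,
            self.a_f,
            self.b_u,
            self.a_u,
            gas_constant=self.gas_constant,
            literal_form=self.literal_form,
        )

    def summary(self) -> str:
        def fmt(name, value, unit=""):
            se = self.bse.get(name)
            se_txt = f" +/- {se:.4g}" if se is not None else ""
            return f"  {name:<4} {value:12.6g}{se_txt} {unit}"

        lines = [
            "Two-state van't Hoff melt fit (ellipticity at 222 nm)",
            f"  points: {self.n_points}   residual RMS: {self.rms:.4g}",
            fmt("Tm", self.tm, f"K  ({self.tm_celsius:.1f} C)"),
            fmt("dH", self.dh, "J mol^-1"),
            fmt("b_f", self.b_f) + ("  [folded intercept]"),
            fmt("a_f", self.a_f) + ("  [folded slope]"),
            fmt("b_u", self.b_u) + ("  [unfolded intercept, fixed]" if self.restrained else "  [unfolded intercept]"),
            fmt("a_u", self.a_u) + ("  [unfolded slope, fixed]" if self.restrained else "  [unfolded slope]"),
        ]
        if self.extrapolated:
            lines.append(
                "  warning: Tm lies outside the measured temperature range "
                "(extrapolated transition)"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.model.curve
        ax.plot(curve.temperatures, curve.ellipticity_222, "o", label="data")
        grid = np.linspace(curve.temperatures[0], curve.temperatures[-1], 300)
        ax.plot(grid, self.predict(grid), "-", label="two-state fit")
        ax.set_xlabel("temperature (K)")
        ax.set_ylabel("ellipticity at 222 nm")
        ax.legend()
        return ax


class MeltModel:
    """Two-state van't Hoff model for one CD melt curve."""

    def __init__(
        self,
        curve: MeltCurve,
        restrain_unfolded_to_zero: bool = False,
        literal_form: bool = False,
        gas_constant: float = GAS_CONSTANT,
    ):
        if curve.temperatures.size < 8:
            raise ValidationError(
                f"melt fit needs >= 8 points, got {curve.temperatures.size}"
            )
        self.curve = curve
        self.restrained = bool(restrain_unfolded_to_zero)
        self.literal_form = bool(literal_form)
        self.gas_constant = float(gas_constant)
        self._t = curve.temperatures
        self._y = curve.ellipticity_222

    @classmethod
    def from_dataframe(cls, df, temperature_unit: str = "K", **kwargs) -> "MeltModel":
        t = df.iloc[:, 0].to_numpy(float)
        if temperature_unit.upper().startswith("C"):
            t = t + 273.15
        return cls(MeltCurve(t, df.iloc[:, 1].to_numpy(float)), **kwargs)

    def _check_identifiable(self) -> float:
        """SSE of a straight line through the melt; flat (linear) data carry
        no transition information."""
        t, y = self._t, self._y
        coeff = np.polyfit(t, y, 1)
        return float(np.sum((y - np.polyval(coeff, t)) ** 2))

    def _residual(self, params: lmfit.Parameters) -> np.ndarray:
        v = params.valuesdict()
        return (
            melt_signal(
                self._t,
                v["tm"],
                v["dh"],
                v["b_f"],
                v["a_f"],
                v["b_u"],
                v["a_u"],
                gas_constant=self.gas_constant,
                literal_form=self.literal_form,
            )
            - self._y
        )

    def _tm_starts(self) -> list[float]:
        t, y = self._t, self._y
        grad = np.gradient(y, t)
        tm_grad = float(t[np.argmax(np.abs(grad))])
        starts = [tm_grad, float(0.5 * (t[0] + t[-1]))]
        if self.restrained:
            starts.insert(0, float(t[-1] + 10.0))
        return starts

    def _baseline_guess(self) -> tuple[float, float, float, float]:
        t, y = self._t, self._y
        k = max(t.size // 3, 2)
        a_f, b_f = np.polyfit(t[:k], y[:k], 1)
        a_u, b_u = np.polyfit(t[-k:], y[-k:], 1)
        return float(b_f), float(a_f), float(b_u), float(a_u)

    def fit(self, seed: int = 0) -> MeltResults:
        t, y = self._t, self._y
        sse_line = self._check_identifiable()
        scale = max(float(np.var(y) * y.size), 1e-30)
        b_f0, a_f0, b_u0, a_u0 = self._baseline_guess()

        best, n_ok, first_init = None, 0, None
        for tm0 in self._tm_starts():
            for dh0 in (300e3, 150e3):
                p = lmfit.Parameters()
                p.add("tm", value=np.clip(tm0, t[0] - 50.0, t[-1] + 150.0),
                      min=t[0] - 50.0, max=t[-1] + 150.0)
                p.add("dh", value=dh0, min=1e3, max=5e6)
                p.add("b_f", value=b_f0)
                p.add("a_f", value=a_f0)
                if self.restrained:
                    p.add("b_u", value=0.0, vary=False)
                    p.add("a_u", value=0.0, vary=False)
                else:
                    p.add("b_u", value=b_u0)
                    p.add("a_u", value=a_u0)
                if first_init is None:
                    first_init = p.valuesdict()
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
                "melt fit failed to converge", initial_values=first_init
            )
        sse_fit = float(best.chisqr)
        improvement = 1.0 - sse_fit / max(sse_line, 1e-30)
        if sse_line <= 1e-12 * scale or improvement < 1e-3:
            raise NonIdentifiableError(
                "melt data are indistinguishable from a straight line; "
                "the van't Hoff enthalpy is not identifiable"
            )
        v = best.params.valuesdict()
        bse = {}
        for short, name in (("Tm", "tm"), ("dH", "dh"), ("b_f", "b_f"),
                            ("a_f", "a_f"), ("b_u", "b_u"), ("a_u", "a_u")):
            par = best.params[name]
            bse[short] = (
                float(par.stderr) if (par.vary and par.stderr is not None) else None
            )
        resid = self._residual(best.params)
        return MeltResults(
            tm=float(v["tm"]),
            dh=float(v["dh"]),
            b_f=float(v["b_f"]),
            a_f=float(v["a_f"]),
            b_u=float(v["b_u"]),
            a_u=float(v["a_u"]),
            bse=bse,
            restrained=self.restrained,
            extrapolated=not (t[0] <= v["tm"] <= t[-1]),
            rms=float(np.sqrt(np.mean(resid**2))),
            n_points=t.size,
            literal_form=self.literal_form,
            gas_constant=self.gas_constant,
            model=self,
        )


def fit_melt(
    curve: MeltCurve, restrain_unfolded_to_zero: bool = False, **kwargs
) -> MeltResults:
    """Functional wrapper: build a :class:`MeltModel` and fit it."""
    return MeltModel(
        curve, restrain_unfolded_to_zero=restrain_unfolded_to_zero, **kwargs
    ).fit()
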