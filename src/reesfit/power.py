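"""Excitation-power planning for extended red-edge measurements.

The absorption (excitation) spectrum of tryptophan falls roughly
exponentially beyond ~300 nm, so holding the emitted intensity constant
while extending the excitation wavelength requires exponentially more
excitation power.  Fitting a line to the log excitation spectrum over a
trusted window and inverting it gives the required power:

    P(lam) = P_ref * exp(c(lam_ref) - c(lam)),

where ``c`` is the fitted log-intensity line and ``P_ref`` the power that
sufficed at the reference wavelength.  ``P_ref`` depends on the instrument
and sample and must be supplied by the user.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError


@dataclass
class ExcitationSpectrum:
    """An excitation spectrum (wavelength nm, intensity a.u.)."""

    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.size != self.intensities.size:
            raise ValidationError("wavelength/intensity length mismatch")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValidationError("wavelengths must be strictly increasing")

    @classmethod
    def from_csv(cls, path) -> "ExcitationSpectrum":
        df = pd.read_csv(path, sep=None, engine="python")
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def required_power(
    spectrum: ExcitationSpectrum,
    fit_window: tuple[float, float],
    target_lambdas,
    reference_power: float,
    reference_lambda: float | None = None,
) -> np.ndarray:
    """Power needed for constant emission intensity at each target wavelength.

    A line is fitted to ``ln(intensity)`` versus wavelength over
    ``fit_window`` (ordinary least squares); the required power at each
    target wavelength scales as the inverse of the extrapolated intensity,
    normalised to ``reference_power`` at ``reference_lambda`` (default: the
    lower edge of the fit window).  The result is invariant to rescaling the
    spectrum's intensity units.
    """
    lo, hi = fit_window
    if not lo < hi:
        raise ValidationError("fit window requires lo < hi")
    mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    if mask.sum() < 3:
        raise ValidationError("fit window must contain at least 3 spectrum points")
    lam = spectrum.wavelengths[mask]
    inten = spectrum.intensities[mask]
    if np.any(inten <= 0):
        raise ValidationError("intensities must be strictly positive inside the fit window")
    ref = float(lo) if reference_lambda is None else float(reference_lambda)
    if not lo <= ref <= hi:
        raise ValidationError("reference wavelength must lie inside the fit window")
    slope, intercept = np.polyfit(lam, np.log(inten), 1)
    targets = np.asarray(target_lambdas, dtype=float)
    log_ratio = (slope * ref + intercept) - (slope * targets + intercept)
    out = reference_power * np.exp(log_ratio)
    return out if out.ndim else float(out)


def power_table(
    spectrum: ExcitationSpectrum,
    fit_window: tuple[float, float],
    target_lambdas,
    reference_power: float,
    reference_lambda: float | None = None,
) -> pd.DataFrame:
    """(wavelength, required power) table for export."""
    targets = np.asarray(target_lambdas, dtype=float)
    power = required_power(
        spectrum, fit_window, targets, reference_power, reference_lambda
    )
    return pd.DataFrame({"excitation_wavelength": targets, "required_power": power})
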