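"""Closed-form models of the red edge excitation shift and of thermal melts.

Two descriptions of a CSM-versus-excitation curve are provided:

* the legacy empirical exponential ("QUBES"),
      CSM(lam_ex) = CSM0 + A * exp(Rc * (lam_ex - lam_ref)),
  a three-parameter description of the low-edge rise with no saturation; and

* the two-state thermodynamic model.  Photoselection by excitation
  wavelength is treated as a two-state equilibrium between the
  Franck-Condon (FC) emissive state and the solvent-relaxed (R) state.
  With a free-energy gap that is linear in excitation wavelength,
      dG(lam_ex) = -m * (lam_ex - lam50),
  the Boltzmann fraction of the relaxed state is
      p = exp(-dG/RT) / (1 + exp(-dG/RT)),
  and the observed CSM is the population-weighted mix of the two baselines
      CSM(lam_ex) = CSM_FC * (1 - p) + CSM_R * p
                  = (CSM_FC + CSM_R * e^x) / (1 + e^x),   x = m (lam_ex - lam50) / RT.

  The asymptotes are exactly CSM_FC (blue edge) and CSM_R (red edge), and
  the curve is monotone for m > 0.  The gradient m (J mol^-1 nm^-1) of the
  linear dG relation is the headline flexibility statistic: a steeper
  transition (larger m) indicates a narrower distribution of
  solvent-fluorophore interaction energies, i.e. a more rigid protein.

A variant in which only the CSM_R term is divided by (1 + e^x) — upper
asymptote CSM_FC + CSM_R — is exposed behind ``literal_form=True`` for
comparison; its high-edge limit is unphysical (the sum of both baselines)
and it is not used by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .exceptions import ModelEvaluationError, ValidationError

logger = logging.getLogger(__name__)

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
DEFAULT_TEMPERATURE = 298.15  # K
_EXP_MAX = 700.0  # exp overflow threshold for float64


@dataclass
class QubesParams:
    """Parameters of the empirical exponential CSM model.

    ``curvature`` is the empirical per-nm exponent (distinct from the gas
    constant); ``reference_lambda`` is the excitation wavelength at which the
    exponential term equals ``amplitude``'s coefficient 1 (usually the lowest
    excitation wavelength measured).
    """

    csm0: float  # nm
    amplitude: float  # nm, >= 0
    curvature: float  # nm^-1
    reference_lambda: float  # nm

    def __post_init__(self):
        if not np.isfinite(self.curvature):
            raise ValidationError("curvature must be finite")
        if self.amplitude < 0:
            raise ValidationError("amplitude must be nonnegative")


@dataclass
class ThermoParams:
    """Parameters of the two-state photoselection model.

    Attributes
    ----------
    csm_fc : float
        CSM of the Franck-Condon baseline (nm); responds to solvent exposure.
    csm_r : float
        CSM of the fully relaxed state (nm); fixed for a fluorophore-solvent
        system (~395-399 nm for tryptophan).
    m : float
        Gradient of the free-energy gap versus excitation wavelength,
        J mol^-1 nm^-1; positive for a red-shifting transition.
    lambda50 : float
        Excitation wavelength (nm) at which the CSM is halfway between the
        baselines (dG = 0).
    temperature : float
        Kelvin.
    gas_constant : float
        J mol^-1 K^-1.
    """

    csm_fc: float
    csm_r: float
    m: float
    lambda50: float
    temperature: float = DEFAULT_TEMPERATURE
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive (Kelvin)")
        if self.csm_r < self.csm_fc:
            raise ValidationError("csm_r must be >= csm_fc")


def qubes_csm(params: QubesParams, lambda_ex):
    """Evaluate the empirical exponential model at ``lambda_ex`` (nm)."""
    lam = np.asarray(lambda_ex, dtype=float)
    exponent = params.curvature * (lam - params.reference_lambda)
    if np.any(exponent > _EXP_MAX):
        raise ModelEvaluationError(
            f"exponential overflow: curvature {params.curvature}/nm at "
            f"excitation offset {np.max(lam - params.reference_lambda)} nm"
        )
    out = params.csm0 + params.amplitude * np.exp(exponent)
    return out if out.ndim else float(out)


def boltzmann_fraction(delta_g, temperature: float, gas_constant: float = GAS_CONSTANT):
    """Fraction of molecules in the relaxed (R) state.

    ``exp(-dG/RT) / (1 + exp(-dG/RT))``, evaluated overflow-safely (logistic
    of ``-dG/RT``); saturates to 0/1 in the extreme-gap limits.
    """
    if temperature <= 0:
        raise ValidationError("temperature must be positive (Kelvin)")
    z = -np.asarray(delta_g, dtype=float) / (gas_constant * temperature)
    out = expit(z)
    return out if out.ndim else float(out)


def delta_g_at(params: ThermoParams, lambda_ex):
    """Free-energy gap FC -> R at ``lambda_ex``: ``-m * (lambda_ex - lambda50)``.

    Zero at the transition midpoint, positive below it (the relaxed state is
    inaccessible at high excitation energy) and decreasing with slope ``-m``.
    Evaluated at the lowest measured excitation wavelength it gives the gap
    at the Franck-Condon reference point.
    """
    lam = np.asarray(lambda_ex, dtype=float)
    out = -params.m * (lam - params.lambda50)
    return out if out.ndim else float(out)


def thermo_csm(params: ThermoParams, lambda_ex, literal_form: bool = False):
    """Two-state CSM sigmoid at ``lambda_ex`` (nm).

    Default is the baseline-weighted form ``CSM_FC*(1-p) + CSM_R*p`` with
    ``p`` the Boltzmann fraction of the relaxed state.  ``literal_form=True``
    leaves the FC term unweighted (upper asymptote ``CSM_FC + CSM_R``); it is
    provided only for comparison.
    """
    lam = np.asarray(lambda_ex, dtype=float)
    x = params.m * (lam - params.lambda50) / (params.gas_constant * params.temperature)
    p = expit(x)
    if literal_form:
        out = params.csm_fc + params.csm_r * p
    else:
        out = params.csm_fc * (1.0 - p) + params.csm_r * p
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# two-state thermal melt (van't Hoff)
# ---------------------------------------------------------------------------


def equilibrium_constant(
    temperature,
    tm: float,
    dh: float,
    gas_constant: float = GAS_CONSTANT,
    literal_sign: bool = False,
):
    """Two-state unfolding equilibrium constant Ku(T).

    Van't Hoff with the unfolding free energy ``dG(T) = dH * (1 - T/Tm)``:

        Ku = exp(-dH * (1 - T/Tm) / (R*T)),

    so ``Ku(Tm) = 1`` exactly, ``Ku < 1`` below the melting temperature
    (folded) and ``Ku > 1`` above it.  ``dH`` is the van't Hoff enthalpy of
    unfolding (J mol^-1) at ``Tm`` (K).  ``literal_sign=True`` drops the
    leading minus (unfolding on cooling) and exists only for comparison.
    The exponent is clipped at the float64 overflow threshold, so the value
    saturates instead of overflowing.
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0) or tm <= 0:
        raise ValidationError("temperatures and Tm must be positive (Kelvin)")
    sign = 1.0 if literal_sign else -1.0
    exponent = np.clip(
        sign * dh * (1.0 - t / tm) / (gas_constant * t), -_EXP_MAX, _EXP_MAX
    )
    out = np.exp(exponent)
    return out if out.ndim else float(out)


def fraction_unfolded(temperature, tm: float, dh: float, gas_constant: float = GAS_CONSTANT):
    """Ku/(1+Ku), evaluated overflow-safely via the logistic of ln(Ku)."""
    t = np.asarray(temperature, dtype=float)
    log_ku = -dh * (1.0 - t / tm) / (gas_constant * t)
    out = expit(log_ku)
    return out if out.ndim else float(out)


def melt_signal(
    temperature,
    tm: float,
    dh: float,
    b_f: float,
    a_f: float,
    b_u: float = 0.0,
    a_u: float = 0.0,
    gas_constant: float = GAS_CONSTANT,
    literal_form: bool = False,
):
    """Two-state melt signal with linear folded/unfolded baselines.

    Default is the standard baseline-weighted form
    ``[(b_f + a_f*T) + (b_u + a_u*T)*Ku] / (1 + Ku)``, i.e. the
    population-weighted mix of the two baselines, whose high-T limit is the
    unfolded baseline alone.  ``literal_form=True`` leaves the folded
    baseline unweighted (high-T limit: sum of both baselines) and is provided
    only for comparison.
    """
    t = np.asarray(temperature, dtype=float)
    fu = fraction_unfolded(t, tm, dh, gas_constant)
    folded = b_f + a_f * t
    unfolded = b_u + a_u * t
    if literal_form:
        out = folded + unfolded * fu
    else:
        out = folded * (1.0 - fu) + unfolded * fu
    return out if out.ndim else float(out)


def resolve_temperature(temperature: float | None) -> float:
    """Return a usable Kelvin temperature, warning when falling back."""
    if temperature is None:
        warnings.warn(
            "no temperature given; assuming 298.15 K", stacklevel=3
        )
        logger.warning("no temperature given; assuming 298.15 K")
        return DEFAULT_TEMPERATURE
    if temperature <= 0:
        raise ValidationError("temperature must be positive (Kelvin)")
    return float(temperature)
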