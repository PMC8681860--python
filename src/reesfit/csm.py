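"""Center of spectral mass (CSM).

The CSM of an emission spectrum is the intensity-weighted mean emission
wavelength,

    CSM = sum(f_i * lambda_i) / sum(f_i),

computed on the discrete instrument grid with no interpolation or
trapezoidal weighting.  Tracked against excitation wavelength it is the
substrate of red-edge-excitation-shift analysis: the CSM red-shifts as the
excitation wavelength photoselects progressively lower-energy, less
solvent-relaxed fluorophore substates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateSpectrumError, ValidationError
from .io import EmissionSpectrum, REESDataset


@dataclass
class CSMCurve:
    """CSM versus excitation wavelength for one sample/condition.

    ``csm_errors`` (optional) are the standard deviations across replicate
    datasets.  ``emission_window`` records the analysis window the CSM values
    were computed over; every CSM necessarily lies inside it.
    """

    excitation_wavelengths: np.ndarray
    csm_values: np.ndarray
    csm_errors: np.ndarray | None = None
    temperature: float | None = None  # Kelvin
    condition: str = ""
    emission_window: tuple[float, float] | None = None

    def __post_init__(self):
        self.excitation_wavelengths = np.asarray(self.excitation_wavelengths, dtype=float)
        self.csm_values = np.asarray(self.csm_values, dtype=float)
        if self.excitation_wavelengths.size != self.csm_values.size:
            raise ValidationError("excitation/CSM length mismatch")
        if not np.all(np.diff(self.excitation_wavelengths) > 0):
            raise ValidationError("excitation wavelengths must be strictly increasing")
        if self.csm_errors is not None:
            self.csm_errors = np.asarray(self.csm_errors, dtype=float)
            if self.csm_errors.size != self.csm_values.size:
                raise ValidationError("csm_errors length mismatch")
            if np.any(self.csm_errors < 0):
                raise ValidationError("csm_errors must be nonnegative")

    def __len__(self) -> int:
        return self.excitation_wavelengths.size

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "excitation_wavelength": self.excitation_wavelengths,
            "csm": self.csm_values,
        }
        if self.csm_errors is not None:
            data["csm_error"] = self.csm_errors
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        temperature: float | None = None,
        condition: str = "",
    ) -> "CSMCurve":
        cols = {c.lower(): c for c in df.columns}
        lam = df[cols.get("excitation_wavelength", df.columns[0])].to_numpy(float)
        csm = df[cols.get("csm", df.columns[1])].to_numpy(float)
        err = None
        if "csm_error" in cols:
            err = df[cols["csm_error"]].to_numpy(float)
        order = np.argsort(lam)
        return cls(
            lam[order],
            csm[order],
            None if err is None else err[order],
            temperature=temperature,
            condition=condition,
        )

    @classmethod
    def from_csv(cls, path, temperature: float | None = None, condition: str = "") -> "CSMCurve":
        return cls.from_dataframe(pd.read_csv(path), temperature=temperature, condition=condition)


def compute_csm(spectrum: EmissionSpectrum, scatter_guard: float | None = None) -> float:
    """Intensity-weighted mean emission wavelength of one spectrum, in nm.

    Parameters
    ----------
    spectrum : EmissionSpectrum
    scatter_guard : float, optional
        If given, emission points with ``lambda_em < lambda_ex + guard`` are
        excluded before the moment is taken, protecting against the Rayleigh
        scatter peak when the spectra were not pre-windowed.  A guard of
        25 nm reproduces the usual 325 nm lower window edge at 292 nm
        excitation.  Fixed emission windows applied upstream are the primary
        mechanism; the guard is a belt-and-braces option.

    Raises
    ------
    DegenerateSpectrumError
        If the total intensity is not strictly positive.
    """
    lam = spectrum.emission_wavelengths
    f = spectrum.intensities
    if scatter_guard is not None:
        mask = lam >= spectrum.excitation_wavelength + scatter_guard
        lam, f = lam[mask], f[mask]
    total = f.sum()
    if not (f.size and np.any(f > 0) and total > 0):
        raise DegenerateSpectrumError(
            "CSM undefined: total intensity is not positive at "
            f"excitation {spectrum.excitation_wavelength} nm"
        )
    return float((f * lam).sum() / total)


def build_csm_curve(
    ds: REESDataset,
    replicates: list[REESDataset] | None = None,
    scatter_guard: float | None = None,
) -> CSMCurve:
    """Compute the CSM at every excitation wavelength of a dataset.

    With ``replicates`` (additional datasets sharing the excitation set), the
    curve carries the mean CSM across all datasets and per-excitation sample
    standard deviations (ddof=1) as ``csm_errors`` — the error bars the field
    reports for 3-5 replicate acquisitions.
    """
    all_ds = [ds] + list(replicates or [])
    lam_ex = ds.excitation_wavelengths
    for other in all_ds[1:]:
        if not np.array_equal(other.excitation_wavelengths, lam_ex):
            raise ValidationError("replicates must share the excitation wavelengths")
    per_ds = []
    for d in all_ds:
        values = []
        for s in d.spectra:
            try:
                values.append(compute_csm(s, scatter_guard=scatter_guard))
            except DegenerateSpectrumError as exc:
                raise DegenerateSpectrumError(
                    f"{exc} (condition {d.condition!r})"
                ) from None
        per_ds.append(values)
    arr = np.asarray(per_ds)  # (n_replicates, n_excitation)
    errors = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else None
    window = (float(ds.emission_wavelengths[0]), float(ds.emission_wavelengths[-1]))
    return CSMCurve(
        lam_ex,
        arr.mean(axis=0),
        errors,
        temperature=ds.temperature,
        condition=ds.condition,
        emission_window=window,
    )
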