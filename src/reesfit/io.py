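"""Spectral and melt table I/O plus dataset assembly.

The on-disk interchange format is a plain delimited table (comma or tab,
auto-detected).  Two layouts are supported for excitation-resolved emission
data:

* **wide** — first column is the emission wavelength in nm, every further
  column holds the intensities recorded at one excitation wavelength; the
  column header is that excitation wavelength in nm.
* **long** — three columns ``excitation``, ``emission``, ``intensity``.

Melt tables are two columns: temperature and ellipticity at 222 nm.

Wavelengths are nm throughout.  Temperatures are accepted in Celsius at the
interfaces (the unit experimentalists report) and stored in Kelvin.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import GridMismatchError, SpectralFormatError, ValidationError

CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(t_celsius: float) -> float:
    return float(t_celsius) + CELSIUS_OFFSET


def kelvin_to_celsius(t_kelvin: float) -> float:
    return float(t_kelvin) - CELSIUS_OFFSET


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class EmissionSpectrum:
    """One steady-state emission trace at a fixed excitation wavelength.

    Parameters
    ----------
    excitation_wavelength : float
        Excitation wavelength in nm.
    emission_wavelengths : array-like
        Strictly increasing emission wavelength grid in nm (length >= 2).
    intensities : array-like
        Fluorescence intensities in arbitrary units, one per grid point.
        Negative values are permitted (they arise after blank subtraction).
    metadata : dict
        Free-form acquisition metadata (temperature K, solvent, slit widths,
        replicate id, ...).
    """

    excitation_wavelength: float
    emission_wavelengths: np.ndarray
    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.excitation_wavelength = float(self.excitation_wavelength)
        self.emission_wavelengths = np.asarray(self.emission_wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        lam, f = self.emission_wavelengths, self.intensities
        if lam.ndim != 1 or lam.size < 2:
            raise ValidationError("emission grid must be 1-D with at least 2 points")
        if lam.size != f.size:
            raise ValidationError(
                f"grid/intensity length mismatch: {lam.size} != {f.size}"
            )
        if not np.all(np.diff(lam) > 0):
            raise ValidationError("emission wavelengths must be strictly increasing")
        if not (np.all(np.isfinite(lam)) and np.all(np.isfinite(f))):
            raise ValidationError("wavelengths and intensities must be finite")

    def windowed(self, lo: float, hi: float) -> "EmissionSpectrum":
        """Restrict the trace to emission wavelengths in ``[lo, hi]`` (nm)."""
        if not lo < hi:
            raise ValidationError(f"window requires lo < hi, got [{lo}, {hi}]")
        mask = (self.emission_wavelengths >= lo) & (self.emission_wavelengths <= hi)
        if not mask.any():
            raise ValidationError(
                f"window [{lo}, {hi}] nm excludes every emission point"
            )
        return EmissionSpectrum(
            self.excitation_wavelength,
            self.emission_wavelengths[mask],
            self.intensities[mask],
            dict(self.metadata),
        )


@dataclass
class REESDataset:
    """A set of emission spectra across excitation wavelengths for one sample.

    Spectra are stored sorted by excitation wavelength and must share an
    identical emission grid (exact wavelength match; no interpolation is
    performed — spectra from a single instrument share a grid, and silent
    resampling would bias the CSM statistic).
    """

    spectra: list[EmissionSpectrum]
    condition: str = ""
    temperature: float | None = None  # Kelvin

    def __post_init__(self):
        if not self.spectra:
            raise ValidationError("dataset needs at least one spectrum")
        self.spectra = sorted(self.spectra, key=lambda s: s.excitation_wavelength)
        lams = [s.excitation_wavelength for s in self.spectra]
        if len(set(lams)) != len(lams):
            dupes = sorted({x for x in lams if lams.count(x) > 1})
            raise SpectralFormatError(f"duplicate excitation wavelengths: {dupes}")
        grid = self.spectra[0].emission_wavelengths
        for s in self.spectra[1:]:
            if (s.emission_wavelengths.size != grid.size) or not np.array_equal(
                s.emission_wavelengths, grid
            ):
                raise GridMismatchError(
                    "all spectra in a dataset must share one emission grid "
                    f"(mismatch at excitation {s.excitation_wavelength} nm)"
                )

    @property
    def excitation_wavelengths(self) -> np.ndarray:
        return np.array([s.excitation_wavelength for s in self.spectra])

    @property
    def emission_wavelengths(self) -> np.ndarray:
        return self.spectra[0].emission_wavelengths

    def intensity_matrix(self) -> np.ndarray:
        """(n_emission, n_excitation) intensity matrix."""
        return np.column_stack([s.intensities for s in self.spectra])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.intensity_matrix(),
            index=self.emission_wavelengths,
            columns=self.excitation_wavelengths,
        )
        df.index.name = "emission_wavelength"
        return df


@dataclass
class MeltCurve:
    """A CD thermal melt: ellipticity at 222 nm versus temperature (Kelvin)."""

    temperatures: np.ndarray
    ellipticity_222: np.ndarray
    condition: str = ""

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.ellipticity_222 = np.asarray(self.ellipticity_222, dtype=float)
        if self.temperatures.size != self.ellipticity_222.size:
            raise ValidationError("temperature/ellipticity length mismatch")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValidationError("temperatures must be strictly increasing")
        if not (
            np.all(np.isfinite(self.temperatures))
            and np.all(np.isfinite(self.ellipticity_222))
        ):
            raise ValidationError("melt data must be finite")


# ---------------------------------------------------------------------------
# delimited-table helpers
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return "\t" if "\t" in sample.splitlines()[0] else ","


def _read_header(path: Path, sep: str) -> list[str]:
    with open(path, "r", newline="") as fh:
        first = fh.readline()
    return next(csv.reader(_io.StringIO(first), delimiter=sep))


def read_spectral_matrix(
    path,
    dialect: str = "wide",
    condition: str = "",
    temperature_celsius: float | None = None,
) -> REESDataset:
    """Read a delimited emission-spectra table into a :class:`REESDataset`.

    ``dialect`` is ``"wide"`` (default) or ``"long"``; the delimiter is
    auto-detected (comma or tab).
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    temperature = (
        celsius_to_kelvin(temperature_celsius)
        if temperature_celsius is not None
        else None
    )
    if dialect == "long":
        return _read_long(path, sep, condition, temperature)
    if dialect != "wide":
        raise SpectralFormatError(f"unknown dialect {dialect!r}")

    header = _read_header(path, sep)
    if len(header) < 2:
        raise SpectralFormatError("wide table needs an emission column plus data")
    lam_ex = []
    for col in header[1:]:
        try:
            lam_ex.append(float(col))
        except ValueError:
            raise SpectralFormatError(
                f"non-numeric excitation-wavelength header {col!r}"
            ) from None
    seen: set[float] = set()
    for x in lam_ex:
        if x in seen:
            raise SpectralFormatError(f"duplicate excitation wavelength header: {x}")
        seen.add(x)

    names = [f"c{i}" for i in range(len(header))]
    try:
        df = pd.read_csv(path, sep=sep, header=None, skiprows=1, names=names,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise SpectralFormatError(f"ragged or malformed table: {exc}") from None
    if df.isna().any().any():
        raise SpectralFormatError("ragged rows or non-numeric cells in table body")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise SpectralFormatError(f"non-numeric table body: {exc}") from None

    lam_em = values[:, 0]
    spectra = [
        EmissionSpectrum(lx, lam_em, values[:, j + 1]) for j, lx in enumerate(lam_ex)
    ]
    return REESDataset(spectra, condition=condition, temperature=temperature)


def _read_long(path: Path, sep: str, condition: str, temperature) -> REESDataset:
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    cols = [c.strip().lower() for c in df.columns]
    want = ("excitation", "emission", "intensity")
    if all(any(w in c for c in cols) for w in want):
        mapping = {w: df.columns[next(i for i, c in enumerate(cols) if w in c)] for w in want}
        df = df[[mapping["excitation"], mapping["emission"], mapping["intensity"]]]
    elif df.shape[1] == 3:
        pass  # positional: λex, λem, intensity
    else:
        raise SpectralFormatError(
            "long table needs columns excitation, emission, intensity"
        )
    df.columns = ["excitation", "emission", "intensity"]
    if df.isna().any().any():
        raise SpectralFormatError("missing values in long table")
    spectra = []
    for lx, sub in df.groupby("excitation", sort=True):
        sub = sub.sort_values("emission")
        spectra.append(
            EmissionSpectrum(lx, sub["emission"].to_numpy(), sub["intensity"].to_numpy())
        )
    return REESDataset(spectra, condition=condition, temperature=temperature)


def write_spectral_matrix(ds: REESDataset, path, sep: str = ",") -> None:
    """Write a dataset as a wide table. ``read(write(ds))`` is bit-exact:
    floats are serialized with ``repr``, which round-trips IEEE doubles."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(
            ["emission_wavelength"] + [repr(x) for x in map(float, ds.excitation_wavelengths)]
        )
        mat = ds.intensity_matrix()
        for i, lam in enumerate(ds.emission_wavelengths):
            writer.writerow([repr(float(lam))] + [repr(float(v)) for v in mat[i]])


def read_melt_table(path, temperature_unit: str = "C", condition: str = "") -> MeltCurve:
    """Read a two-column (temperature, ellipticity) delimited table.

    ``temperature_unit`` is ``"C"`` (default, converted to K) or ``"K"``.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    header = _read_header(path, sep)
    has_header = False
    try:
        float(header[0])
    except ValueError:
        has_header = True
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None,
                     float_precision="round_trip")
    if df.shape[1] < 2:
        raise SpectralFormatError("melt table needs two columns (T, ellipticity)")
    temps = df.iloc[:, 0].to_numpy(dtype=float)
    signal = df.iloc[:, 1].to_numpy(dtype=float)
    if temperature_unit.upper().startswith("C"):
        temps = temps + CELSIUS_OFFSET
    elif not temperature_unit.upper().startswith("K"):
        raise ValidationError(f"unknown temperature unit {temperature_unit!r}")
    order = np.argsort(temps)
    return MeltCurve(temps[order], signal[order], condition=condition)


# ---------------------------------------------------------------------------
# dataset operations
# ---------------------------------------------------------------------------


def subtract_blank(
    sample: REESDataset, blank: REESDataset, clip_negative: bool = False
) -> REESDataset:
    """Subtract a buffer-blank dataset from a sample, excitation by excitation.

    Both datasets must share the excitation set and the emission grid exactly.
    Negative differences are kept by default (CSM weighting with clipped zeros
    is better behaved, and clipping biases the statistic); pass
    ``clip_negative=True`` to floor at zero.
    """
    s_lams = set(sample.excitation_wavelengths.tolist())
    b_lams = set(blank.excitation_wavelengths.tolist())
    if s_lams != b_lams:
        missing = sorted(s_lams.symmetric_difference(b_lams))
        raise GridMismatchError(
            f"sample and blank excitation sets differ; unmatched wavelengths: {missing}"
        )
    if not np.array_equal(sample.emission_wavelengths, blank.emission_wavelengths):
        raise GridMismatchError("sample and blank emission grids differ")
    blank_by_lam = {s.excitation_wavelength: s for s in blank.spectra}
    out = []
    for s in sample.spectra:
        diff = s.intensities - blank_by_lam[s.excitation_wavelength].intensities
        if clip_negative:
            diff = np.maximum(diff, 0.0)
        meta = dict(s.metadata)
        meta["blank_subtracted"] = True
        meta["clip_negative"] = bool(clip_negative)
        out.append(EmissionSpectrum(s.excitation_wavelength, s.emission_wavelengths, diff, meta))
    return REESDataset(out, condition=sample.condition, temperature=sample.temperature)


def window_emission(ds: REESDataset, lo: float, hi: float) -> REESDataset:
    """Restrict every spectrum to emission wavelengths in ``[lo, hi]`` nm.

    The standard analysis window is 325-500 nm, which keeps the emission band
    clear of first- and second-order scatter artifacts of the excitation line.
    """
    spectra = [s.windowed(lo, hi) for s in ds.spectra]
    return REESDataset(spectra, condition=ds.condition, temperature=ds.temperature)
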