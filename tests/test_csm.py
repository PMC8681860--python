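import numpy as np
import pytest
from hypothesis import given, strategies as st

import reesfit as rf
from reesfit.exceptions import DegenerateSpectrumError

from conftest import random_spectrum


def brute_force_csm(spectrum):
    """Independent loop oracle for the intensity-weighted mean wavelength."""
    num = 0.0
    den = 0.0
    for lam, f in zip(spectrum.emission_wavelengths, spectrum.intensities):
        num += f * lam
        den += f
    return num / den


@pytest.mark.parametrize(
    "lam,f,expected",
    [
        ([340.0, 350.0, 360.0], [0.0, 7.0, 0.0], 350.0),  # point mass
        ([340.0, 350.0, 360.0], [2.0, 2.0, 2.0], 350.0),  # symmetry
        ([340.0, 360.0], [1.0, 3.0], 355.0),  # hand-evaluated weighted mean
    ],
)
def test_csm_examples(lam, f, expected):
    s = rf.EmissionSpectrum(292.0, lam, f)
    assert rf.compute_csm(s) == pytest.approx(expected, abs=1e-12)


def test_csm_matches_brute_force_oracle(rng):
    for _ in range(200):
        s = random_spectrum(rng)
        assert rf.compute_csm(s) == pytest.approx(
            brute_force_csm(s), rel=1e-12
        )


@given(scale=st.floats(1e-6, 1e6), shift=st.floats(-50.0, 50.0))
def test_csm_scale_invariance_and_shift_equivariance(scale, shift):
    rng = np.random.default_rng(7)
    lam = np.sort(rng.uniform(320, 500, 25))
    f = rng.uniform(0.1, 10.0, 25)
    base = rf.compute_csm(rf.EmissionSpectrum(292.0, lam, f))
    scaled = rf.compute_csm(rf.EmissionSpectrum(292.0, lam, f * scale))
    shifted = rf.compute_csm(rf.EmissionSpectrum(292.0, lam + shift, f))
    assert scaled == pytest.approx(base, rel=1e-9)
    assert shifted == pytest.approx(base + shift, rel=1e-12, abs=1e-9)


@pytest.mark.parametrize("bad", [[0.0, 0.0, 0.0], [-1.0, -2.0, -3.0], [3.0, -4.0, 0.0]])
def test_degenerate_spectra_rejected(bad):
    s = rf.EmissionSpectrum(292.0, [340.0, 350.0, 360.0], bad)
    with pytest.raises(DegenerateSpectrumError):
        rf.compute_csm(s)


def test_scatter_guard_drops_leading_points():
    # a scatter spike below lam_ex + guard must not drag the CSM
    lam = np.array([300.0, 340.0, 360.0])
    f = np.array([1000.0, 1.0, 1.0])
    s = rf.EmissionSpectrum(292.0, lam, f)
    assert rf.compute_csm(s, scatter_guard=25.0) == pytest.approx(350.0)


class TestBuildCurve:
    def test_identical_spectra_give_constant_curve(self):
        lam_em = np.arange(330.0, 401.0)
        f = np.exp(-((lam_em - 360.0) ** 2) / 400.0)
        spectra = [rf.EmissionSpectrum(x, lam_em, f) for x in (292.0, 293.0, 294.0)]
        curve = rf.build_csm_curve(rf.REESDataset(spectra))
        assert np.ptp(curve.csm_values) == pytest.approx(0.0, abs=1e-12)

    def test_identical_replicates_give_zero_errors(self):
        lam_em = np.arange(330.0, 401.0)
        f = np.exp(-((lam_em - 360.0) ** 2) / 400.0)
        ds = rf.REESDataset(
            [rf.EmissionSpectrum(x, lam_em, f) for x in (292.0, 293.0)]
        )
        curve = rf.build_csm_curve(ds, replicates=[ds, ds])
        assert curve.csm_errors is not None
        np.testing.assert_allclose(curve.csm_errors, 0.0, atol=1e-12)

    def test_degenerate_excitation_named(self):
        lam_em = np.arange(330.0, 340.0)
        good = np.ones(lam_em.size)
        ds = rf.REESDataset(
            [
                rf.EmissionSpectrum(292.0, lam_em, good),
                rf.EmissionSpectrum(293.0, lam_em, np.zeros(lam_em.size)),
            ]
        )
        with pytest.raises(DegenerateSpectrumError, match="293"):
            rf.build_csm_curve(ds)

    def test_generator_round_trip(self, noiseless_dataset):
        ds, truth = noiseless_dataset
        curve = rf.build_csm_curve(ds)
        targets = rf.thermo_csm(truth, curve.excitation_wavelengths)
        assert np.max(np.abs(curve.csm_values - targets)) < 0.05


def test_curve_csv_round_trip(tmp_path):
    curve = rf.generate_csm_curve(noise_sd=0.1, seed=5)
    path = tmp_path / "curve.csv"
    curve.to_csv(path)
    back = rf.CSMCurve.from_csv(path, temperature=298.15)
    np.testing.assert_allclose(back.csm_values, curve.csm_values)
    np.testing.assert_allclose(back.excitation_wavelengths, curve.excitation_wavelengths)
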