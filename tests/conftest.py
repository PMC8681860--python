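import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import reesfit as rf

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def solution_truth():
    """Solution-tryptophan-like ground truth (transition near the window)."""
    return rf.DEFAULT_TRUTH


@pytest.fixture(scope="session")
def protein_truth():
    from reesfit.studies import PROTEIN_TRUTH

    return PROTEIN_TRUTH


@pytest.fixture(scope="session")
def noiseless_dataset(solution_truth):
    """One noiseless synthetic spectral dataset plus its ground truth."""
    spec = rf.SyntheticSpec(thermo=solution_truth, noise_sd=0.0, seed=11)
    datasets, truth = rf.generate_rees_dataset(spec)
    return datasets[0], truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20230917)


def random_spectrum(rng, n_min=2, n_max=60):
    n = int(rng.integers(n_min, n_max))
    lam = np.sort(rng.uniform(300.0, 550.0, n))
    lam += np.arange(n) * 1e-6  # enforce strict increase
    f = rng.uniform(0.01, 100.0, n)
    return rf.EmissionSpectrum(300.0 - 10.0, lam, f)
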