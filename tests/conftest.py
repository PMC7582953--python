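"""Shared fixtures: small synthetic datasets with known ground truth."""

import numpy as np
import pytest

from tfpdyn.fitting import fit_diffusion
from tfpdyn.simulate import DynamicsProfileSpec, make_profile, simulate_dataset


@pytest.fixture(scope="session")
def noiseless_spec():
    """Small noiseless study: 60 residues, tau_R 4.3 ns, two fields.

    Reported uncertainties stay at the nominal floor so chi^2 weighting
    is defined; the values themselves are exact forward-model output.
    """
    return DynamicsProfileSpec(
        n_residues=60, noise_rate_frac=0.0, noise_noe_abs=0.0, seed=7
    )


@pytest.fixture(scope="session")
def noiseless_truth(noiseless_spec):
    return make_profile(noiseless_spec)


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_spec, noiseless_truth):
    return simulate_dataset(noiseless_truth, noiseless_spec)


@pytest.fixture(scope="session")
def noiseless_tensor(noiseless_dataset):
    return fit_diffusion(noiseless_dataset)


@pytest.fixture(scope="session")
def noisy_spec():
    """The packaged noisy preset at reduced size for unit tests."""
    return DynamicsProfileSpec(n_residues=60, seed=11)


@pytest.fixture(scope="session")
def noisy_truth(noisy_spec):
    return make_profile(noisy_spec)


@pytest.fixture(scope="session")
def noisy_dataset(noisy_spec, noisy_truth):
    return simulate_dataset(noisy_truth, noisy_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
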