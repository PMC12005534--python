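import numpy as np
import pytest

from intentchain.session_model import ExperimentConfig
from intentchain.synthetic_data import GeneratorParams, generate_session_with_truth


@pytest.fixture(scope="session")
def config():
    return ExperimentConfig()


@pytest.fixture(scope="session")
def small_session():
    """A reduced session (10 trials/condition, 16 channels, 12 units)
    shared by tests that only need structural realism, with the
    generator's latent ground truth."""
    params = GeneratorParams(
        n_trials_per_condition=10,
        n_channels=16,
        n_sorted_units=12,
        lfp_channels=1,
        seed=7,
    )
    bundle, truth = generate_session_with_truth(params, seed=7)
    return bundle, truth


@pytest.fixture(scope="session")
def small_params():
    return GeneratorParams(
        n_trials_per_condition=10,
        n_channels=16,
        n_sorted_units=12,
        lfp_channels=1,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
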