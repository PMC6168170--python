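import numpy as np
import pytest

from tslandscape import models
from tslandscape.experiments import dev_branch_states


@pytest.fixture(scope="session")
def toy_params():
    return models.ToyParams()


@pytest.fixture(scope="session")
def dev_params():
    return models.load_params("calibrated")


@pytest.fixture(scope="session")
def dev_branches_L50(dev_params):
    """Stem / transition / differentiated fixed points at L = 50 (expensive)."""
    return dev_branch_states(dev_params.replace(L=50.0), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_toy_points(n, scale=1.5, seed=0):
    return np.random.default_rng(seed).uniform(-scale, scale, size=(n, 2))


def random_dev_states(n, high=150.0, seed=0):
    return np.random.default_rng(seed).uniform(0.0, high, size=(n, 4))
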