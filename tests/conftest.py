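import numpy as np
import pytest
from hypothesis import settings

import repsync

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def theta_star():
    return repsync.reference_chaotic_params()


@pytest.fixture(scope="session")
def obs_clean(theta_star):
    """Clean two-channel observations from the reference chaotic system."""
    return repsync.simulate_observations(theta_star, seed=0)


@pytest.fixture(scope="session")
def y0_alt():
    """A secondary initial condition distinct from the shipped default."""
    return repsync.default_initial_state() * 1.3 + 1.0


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
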