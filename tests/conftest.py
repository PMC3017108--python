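import logging

import numpy as np
import pytest

from cryptsim import make_fixture, mini_crypt_params, simulate
from cryptsim.params import ModelParams

logging.getLogger("cryptsim").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def reference_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def mini_params() -> ModelParams:
    return mini_crypt_params()


@pytest.fixture(scope="session")
def mini_state():
    """Freshly initialised (relaxed, unstepped) mini crypt."""
    return make_fixture("mini_crypt", seed=11)


@pytest.fixture(scope="session")
def mini_run():
    """A 10-day mini-crypt run (reaches steady state): (state, trajectory)."""
    state = make_fixture("mini_crypt", seed=11)
    traj = simulate(state, 240.0, observer_interval=3.0)
    return state, traj


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
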