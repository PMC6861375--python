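import numpy as np
import pytest

import ratephase as rp


@pytest.fixture(scope="session")
def cell0():
    return rp.default_cell(0.0)


@pytest.fixture(scope="session")
def cell15():
    return rp.default_cell(1.5)


@pytest.fixture(scope="session")
def syn():
    return rp.default_synapse()


@pytest.fixture(scope="session")
def current_10hz(cell0):
    """Mean input at which the isolated low-g_ks cell fires 10 Hz."""
    return rp.calibrate_mean_input(cell0, 10.0)


@pytest.fixture(scope="session")
def small_net():
    """A 40E + 10I network, enough structure for fast integration tests."""
    return rp.generate_network(7, n_e=40, n_i=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
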