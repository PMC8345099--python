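import numpy as np
import pytest

from enhancerkit import SimulationConfig, simulate_chip


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def default_chip():
    """One chip simulation at study-default settings, shared across tests."""
    return simulate_chip(SimulationConfig(seed=11))


@pytest.fixture
def small_config():
    """A scaled-down simulation for fast unit tests."""
    return SimulationConfig(
        seed=5,
        n_common=20,
        n_up=8,
        n_down=8,
        n_genes=30,
        n_shrnas=170,
        n_depleted=2,
    )
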