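import numpy as np
import pytest

from operonet.simulate import SimConfig, sim_to_dataset, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_sim():
    """A small default-condition simulation shared across tests."""
    return simulate(SimConfig(seed=3, n_genes=40, n_samples=2))


@pytest.fixture(scope="session")
def small_dataset(small_sim):
    return sim_to_dataset(small_sim)
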