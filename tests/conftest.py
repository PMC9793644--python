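import numpy as np
import pytest

from circstack import PropertyTable, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def table() -> PropertyTable:
    return PropertyTable.default()


@pytest.fixture(scope="session")
def small_dataset():
    """A small strongly separable simulated dataset shared across tests."""
    cfg = SimulationConfig(n_pos=60, n_neg=60, length_range=(200, 800), seed=7)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
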