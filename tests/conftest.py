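import numpy as np
import pytest

from mspls import (
    MultiBlockDataset,
    OmicsBlock,
    SimulationConfig,
    simulate_dataset,
    three_block_connectivity,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def C3():
    return three_block_connectivity()


@pytest.fixture
def toy_sim():
    """Small associated three-block dataset (n=30, p=(6,6,4))."""
    return simulate_dataset(
        SimulationConfig(n=30, p=(6, 6, 4), k=(3, 3, 2), seed=101)
    )


@pytest.fixture
def toy_dataset3(toy_sim):
    return toy_sim.dataset


def make_dataset(rng, n, ps, names=None):
    names = names or [f"B{i + 1}" for i in range(len(ps))]
    blocks = [
        OmicsBlock(name, rng.standard_normal((n, p))) for name, p in zip(names, ps)
    ]
    return MultiBlockDataset(blocks).standardize()


@pytest.fixture
def make_random_dataset(rng):
    def _make(n, ps, names=None):
        return make_dataset(rng, n, ps, names)

    return _make
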