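import numpy as np
import pytest

from dynconn.networks import NetworkDefinition


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_map():
    """Eight ROIs split over the four named networks (2 each)."""
    return NetworkDefinition.evenly_partitioned(8)


@pytest.fixture
def two_block_map():
    """Eight ROIs in two 4-ROI networks (larger within-network blocks)."""
    return NetworkDefinition.evenly_partitioned(8, names=("netA", "netB"))


def random_adjacency(rng, n, density):
    """Symmetric 0/1 adjacency with zero diagonal."""
    upper = rng.random((n, n)) < density
    a = np.triu(upper, 1)
    a = (a | a.T).astype(np.int8)
    return a


@pytest.fixture
def adjacency_factory():
    return random_adjacency
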