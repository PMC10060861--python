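import numpy as np
import pytest
from hypothesis import settings

from sysseg_pain.atlas import PartitionAtlas

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_net_atlas():
    """4 nodes, two 2-node networks (the smallest legal partition)."""
    return PartitionAtlas(("a1", "a2", "b1", "b2"), ("A", "A", "B", "B"))


@pytest.fixture
def small_atlas():
    """10 nodes across three networks, for brute-force oracle checks."""
    nets = ("A",) * 4 + ("B",) * 3 + ("C",) * 3
    return PartitionAtlas(tuple(f"n{i}" for i in range(10)), nets)


def random_fc(n_nodes, rng):
    """Random symmetric nonnegative z-matrix with zero diagonal."""
    z = np.abs(rng.normal(0.3, 0.2, size=(n_nodes, n_nodes)))
    z = (z + z.T) / 2
    np.fill_diagonal(z, 0.0)
    return z
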