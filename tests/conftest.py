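import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from supernodes import Graph, planted_partition_graph


@pytest.fixture
def two_triangles() -> Graph:
    """Triangles {0,1,2} and {3,4,5} joined by the bridge edge 2-3."""
    return Graph(6, [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4), (3, 5), (4, 5)])


@pytest.fixture
def disjoint_triangles() -> Graph:
    return Graph(6, [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)])


@pytest.fixture
def path5() -> Graph:
    """Path graph 0-1-2-3-4."""
    return Graph(5, [(0, 1), (1, 2), (2, 3), (3, 4)])


@pytest.fixture
def small_planted():
    """A quickly solvable planted-partition fixture with strong structure.

    n is chosen so block sizes differ (107, 107, 106): community-size node
    rankings then carry information, keeping Kendall-tau matching
    well-defined.
    """
    return planted_partition_graph(320, 3, 0.15, 0.01, rng_seed=5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
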