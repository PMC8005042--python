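import numpy as np
import pytest

from multignn.featurization import build_schema
from multignn.fixtures import SyntheticSpec, make_dataset


@pytest.fixture(scope="session")
def schema():
    return build_schema()


@pytest.fixture(scope="session")
def fixture_molecules():
    """50 synthetic molecules with noiseless labels (shared, read-only)."""
    return make_dataset(SyntheticSpec(n_molecules=50, seed=11, sigma=0.0))


@pytest.fixture(scope="session")
def noisy_dataset():
    """The standard learnability dataset: 200 molecules, sigma = 0.2."""
    return make_dataset(SyntheticSpec(n_molecules=200, seed=7, sigma=0.2))


def random_graph(rng: np.random.Generator, max_nodes: int = 8,
                 width: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Random small graph: features (n, width) and directed COO edges."""
    n = int(rng.integers(2, max_nodes + 1))
    pairs = [(u, v) for u in range(n) for v in range(u + 1, n)
             if rng.random() < 0.5]
    edges = []
    for u, v in pairs:
        edges.append((u, v))
        edges.append((v, u))
    edge_index = (np.array(edges, dtype=np.int64).T if edges
                  else np.zeros((2, 0), dtype=np.int64))
    return rng.normal(size=(n, width)), edge_index


def dense_adjacency(edge_index: np.ndarray, n: int) -> np.ndarray:
    a = np.zeros((n, n))
    for u, v in edge_index.T:
        a[u, v] = 1.0
    return a
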