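import numpy as np
import pytest
from hypothesis import settings

from dfinder.graph import BipartiteDFIGraph
from dfinder.synthetic import generate_fixture

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def tiny_graph() -> BipartiteDFIGraph:
    """3 drugs x 3 foods, 4 edges; D1 has degree 2."""
    return BipartiteDFIGraph.from_edges(
        [("D1", "F1"), ("D1", "F2"), ("D2", "F2"), ("D3", "F3")]
    )


def random_bipartite(rng: np.random.Generator, max_nodes: int = 30) -> BipartiteDFIGraph:
    """Random bipartite graph with at least one edge, for property tests."""
    M = int(rng.integers(2, max_nodes // 2 + 1))
    N = int(rng.integers(2, max_nodes // 2 + 1))
    p = rng.uniform(0.1, 0.5)
    mask = rng.random((M, N)) < p
    if not mask.any():
        mask[rng.integers(M), rng.integers(N)] = True
    drugs = [f"D{i}" for i in range(M)]
    foods = [f"F{j}" for j in range(N)]
    edges = [(drugs[i], foods[j]) for i, j in np.argwhere(mask)]
    return BipartiteDFIGraph(drugs, foods, edges)


@pytest.fixture(scope="session")
def small_fixture():
    """Small planted-structure fixture shared by the slower model tests."""
    return generate_fixture(
        M=30, N=40, d_lat=4, target_density=0.08, ssp_dim=32, noise_sd=0.1, seed=1
    )
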