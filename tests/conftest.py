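import numpy as np
import pytest

import ssecluster as sc


@pytest.fixture(scope="session")
def barbell6() -> sc.CellGraph:
    """Two unit-weight triangles joined by one bridge edge (n=6, 2e=14)."""
    return sc.generate_toy_graph("barbell", 3)


@pytest.fixture(scope="session")
def two_triangles() -> sc.CellGraph:
    """Two disjoint unit-weight triangles."""
    return sc.generate_toy_graph("two_cliques", 3)


@pytest.fixture(scope="session")
def strong_dataset() -> sc.SyntheticDataset:
    """Strong-preset planted dataset, 3 x 20 cells x 500 genes, seed 1."""
    return sc.generate_planted_expression(sc.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def two_block_dataset() -> sc.SyntheticDataset:
    """Planted 2-block dataset, 40 cells, seed 1."""
    return sc.generate_planted_expression(
        sc.SyntheticConfig(n_cells=40, cluster_sizes=(20, 20), seed=1)
    )


def random_weighted_graph(n: int, seed: int, density: float = 0.5) -> sc.CellGraph:
    """Seeded random weighted graph guaranteed to have at least one edge."""
    rng = np.random.default_rng(seed)
    U = np.triu(rng.random((n, n)) * (rng.random((n, n)) < density), k=1)
    if U.sum() == 0:
        U[0, 1] = rng.random() + 0.1
    W = U + U.T
    return sc.CellGraph(node_ids=[f"n{i}" for i in range(n)], W=W)
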