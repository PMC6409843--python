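"""Weighted undirected cell network built from the learned similarity.

Every strictly positive learned similarity becomes an edge ("reserve all
values"): the sparsity of the network comes from the simplex projection in
the similarity step, not from a k-nearest-neighbour cutoff.  Self
similarities are always dropped because self-loops distort the
degree-based entropy downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse
import scipy.sparse.csgraph

from .exceptions import GraphError, InputError
from .similarity import SimilarityModel

__all__ = ["CellGraph", "build_cell_graph", "connected_components"]


@dataclass
class CellGraph:
    """Weighted undirected graph over cells.

    ``W`` is symmetric nonnegative with an exactly-zero diagonal;
    ``degrees`` are weighted degrees (strengths) and ``total_volume`` is
    2e = sum of degrees = twice the total edge weight.
    """

    node_ids: list[str]
    W: np.ndarray
    degrees: np.ndarray = field(init=False)
    total_volume: float = field(init=False)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = self.W.shape[0]
        if self.W.shape != (n, n):
            raise InputError("weight matrix must be square")
        if len(self.node_ids) != n:
            raise InputError(f"{len(self.node_ids)} node ids for {n} nodes")
        if np.any(self.W < 0):
            raise InputError("edge weights must be nonnegative")
        if not np.allclose(self.W, self.W.T, atol=1e-12):
            raise InputError("weight matrix must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise InputError("diagonal must be exactly zero")
        self.degrees = self.W.sum(axis=1)
        self.total_volume = float(self.degrees.sum())

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.W, k=1)))

    def edge_list(self) -> list[tuple[str, str, float]]:
        """(cell_a, cell_b, weight) triples over the upper triangle."""
        rows, cols = np.nonzero(np.triu(self.W, k=1))
        return [
            (self.node_ids[i], self.node_ids[j], float(self.W[i, j]))
            for i, j in zip(rows, cols)
        ]


def build_cell_graph(
    S: SimilarityModel | np.ndarray,
    node_ids: list[str] | None = None,
    knn_truncate: int | None = None,
) -> CellGraph:
    """Symmetrize a similarity matrix into a cell graph.

    W = (S + S^T) / 2 with the diagonal zeroed; every positive entry is
    kept as an edge.  ``knn_truncate`` optionally keeps only the top-k
    entries of each row *before* symmetrization, for callers that feed a
    dense matrix; it is off by default.
    """
    A = S.S if isinstance(S, SimilarityModel) else np.asarray(S, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n):
        raise InputError("similarity matrix must be square")
    if np.any(A < 0):
        raise InputError("similarity entries must be nonnegative")
    if node_ids is None:
        node_ids = [f"cell_{i}" for i in range(n)]
    if len(node_ids) != n:
        raise InputError("node id count does not match matrix dimension")

    A = A.copy()
    if knn_truncate is not None:
        if knn_truncate < 1:
            raise InputError("knn_truncate must be >= 1")
        k = min(knn_truncate, n - 1)
        np.fill_diagonal(A, 0.0)
        # zero everything below each row's k-th largest entry
        thresh = -np.partition(-A, k - 1, axis=1)[:, k - 1]
        A[A < thresh[:, None]] = 0.0

    W = (A + A.T) / 2.0
    np.fill_diagonal(W, 0.0)
    G = CellGraph(node_ids=list(node_ids), W=W)
    if G.total_volume <= 0:
        raise GraphError("graph has no edges (total volume is zero)")
    return G


def connected_components(G: CellGraph) -> list[list[int]]:
    """Components over strictly positive edges, ordered by smallest member."""
    sp = scipy.sparse.csr_matrix(G.W)
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        sp, directed=False
    )
    comps: dict[int, list[int]] = {}
    for node, lab in enumerate(labels):
        comps.setdefault(int(lab), []).append(node)
    return sorted(comps.values(), key=lambda members: members[0])
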