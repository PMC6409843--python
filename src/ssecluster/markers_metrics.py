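"""Marker-gene ranking per community and partition agreement metrics.

Marker selection is purely mean-based: each gene is assigned to the
community with the highest mean expression over that community's cells,
and within a community its genes are ranked by descending mean.  Partition
agreement uses normalized mutual information (NMI, base-2 logs) and the
adjusted Rand index (ARI), both computed from the contingency table of the
two labelings.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .entropy import Partition
from .exceptions import InputError
from .similarity import ExpressionMatrix

__all__ = [
    "MarkerGeneTable",
    "ContingencyTable",
    "community_mean_expression",
    "rank_marker_genes",
    "contingency",
    "nmi",
    "ari",
]


@dataclass
class MarkerGeneTable:
    """Gene-to-community assignment plus per-community top-k rankings.

    ``assignment[g]`` is the community whose mean expression of gene g is
    highest; ``per_community_rankings[l]`` lists up to top_k gene ids of
    community l in non-increasing mean order; ``means`` is the full
    communities x genes mean-expression matrix.
    """

    assignment: np.ndarray
    per_community_rankings: list[list[str]]
    means: np.ndarray
    gene_ids: list[str]

    def to_rows(self) -> list[tuple[int, int, str, float]]:
        """(community, rank, gene_id, mean_expression) rows for export."""
        gi = {g: j for j, g in enumerate(self.gene_ids)}
        rows = []
        for l, ranking in enumerate(self.per_community_rankings):
            for r, gene in enumerate(ranking, start=1):
                rows.append((l, r, gene, float(self.means[l, gi[gene]])))
        return rows


@dataclass
class ContingencyTable:
    """Co-assignment counts n_ij between two labelings of n elements."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def community_mean_expression(X: ExpressionMatrix, P: Partition) -> np.ndarray:
    """Mean expression of every gene within every community (L x genes)."""
    if P.n != X.n_cells:
        raise InputError(
            f"partition covers {P.n} cells but matrix has {X.n_cells}"
        )
    return np.stack([X.values[idx].mean(axis=0) for idx in P.members])


def rank_marker_genes(
    X: ExpressionMatrix, P: Partition, top_k: int = 10
) -> MarkerGeneTable:
    """Assign genes to communities by argmax mean; rank within community.

    Ties in the argmax go to the lowest community index; ties in the
    within-community sort go to the lower gene index.  Each community
    reports at most ``top_k`` genes (fewer if it owns fewer).
    """
    if top_k < 0:
        raise InputError("top_k must be >= 0")
    means = community_mean_expression(X, P)
    assignment = np.argmax(means, axis=0)  # ties -> lowest community index
    rankings: list[list[str]] = []
    for l in range(P.num_communities):
        owned = np.flatnonzero(assignment == l)
        order = sorted(owned, key=lambda g: (-means[l, g], g))
        rankings.append([X.gene_ids[g] for g in order[:top_k]])
    return MarkerGeneTable(
        assignment=assignment,
        per_community_rankings=rankings,
        means=means,
        gene_ids=list(X.gene_ids),
    )


def contingency(a, b) -> ContingencyTable:
    """Contingency table of two equal-length label vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("label vectors must be one-dimensional, equal length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    counts = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(counts, (ai, bi), 1)
    return ContingencyTable(counts)


def nmi(a, b) -> float:
    """Normalized mutual information 2 I(X;Y) / (H(X) + H(Y)) in [0, 1].

    If both labelings are single-cluster (zero entropy on both sides) the
    partitions are identical, so 1.0; if exactly one side has zero entropy
    there is no shared information to normalize, so 0.0.
    """
    tab = contingency(a, b).counts.astype(float)
    n = tab.sum()
    pxy = tab / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)

    def H(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    hx, hy = H(px), H(py)
    if hx == 0.0 and hy == 0.0:
        return 1.0
    if hx == 0.0 or hy == 0.0:
        return 0.0
    nz = pxy > 0
    outer = px[:, None] * py[None, :]
    I = float((pxy[nz] * np.log2(pxy[nz] / outer[nz])).sum())
    return 2.0 * I / (hx + hy)


def ari(a, b) -> float:
    """Adjusted Rand index from the contingency table (exact integer sums).

    ARI = (Index - Expected) / (Max - Expected) with Index =
    sum_ij C(n_ij, 2), Expected = sum_i C(a_i,2) sum_j C(b_j,2) / C(n,2),
    Max = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2.  A zero denominator
    (both all-singletons or both single-cluster) means the two labelings
    agree trivially: 1.0.
    """
    tab = contingency(a, b)
    n = tab.n
    if n < 2:
        raise InputError("ARI needs at least 2 elements")
    index = sum(comb(int(x), 2) for x in tab.counts.ravel())
    sum_a = sum(comb(int(x), 2) for x in tab.row_sums)
    sum_b = sum(comb(int(x), 2) for x in tab.col_sums)
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((index - expected) / (max_index - expected))
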