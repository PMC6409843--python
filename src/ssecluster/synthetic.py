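"""Seeded synthetic data: planted-cluster expression matrices, toy graphs.

The expression generator emulates the two statistical features the
clustering method actually relies on: dropout-driven sparsity (technical
zeros reaching ~50% of entries) and separable cluster structure (each
planted cluster over-expresses its own block of marker genes).  Baseline
expression is log-normal in base 2 -- ``x = 2**Normal(mu0, dispersion)``
-- with the marker block's log2-mean elevated by ``effect``; entries are
then independently zeroed with probability ``dropout_rate``.  Library-size
variation, batch effects and trajectories are deliberately not modelled.

Toy graphs (cliques, barbell, ring, planted blocks) serve the entropy
module's oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError
from .graph import CellGraph
from .similarity import ExpressionMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_planted_expression",
    "generate_toy_graph",
]

#: log2-scale baseline mean expression of a non-marker gene
BASELINE_LOG2_MEAN = 1.0


@dataclass
class SyntheticConfig:
    """Planted-cluster expression generator parameters ("strong" preset).

    Defaults are the study conditions used throughout the test-suite:
    3 clusters x 20 cells x 500 genes, 50 marker genes per cluster whose
    log2-mean is elevated by ``effect`` = 2 (a four-fold change), log2
    dispersion 0.5 and 50% dropout.  The preset emulates a clean,
    well-separated population structure in which a large fraction of the
    measured transcriptome is subpopulation-specific, and is calibrated so
    the full pipeline recovers the planted labels.
    """

    n_cells: int = 60
    n_genes: int = 500
    cluster_sizes: tuple[int, ...] = (20, 20, 20)
    markers_per_cluster: int = 50
    effect: float = 2.0
    dispersion: float = 0.5
    dropout_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ConfigError("n_cells and n_genes must be positive")
        if any(s < 1 for s in self.cluster_sizes):
            raise ConfigError("cluster sizes must be positive")
        if sum(self.cluster_sizes) != self.n_cells:
            raise ConfigError(
                f"cluster_sizes sum {sum(self.cluster_sizes)} != n_cells "
                f"{self.n_cells}"
            )
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ConfigError("dropout_rate must be in [0, 1]")
        if self.markers_per_cluster < 0:
            raise ConfigError("markers_per_cluster must be >= 0")
        if self.markers_per_cluster * len(self.cluster_sizes) > self.n_genes:
            raise ConfigError("marker blocks exceed the number of genes")


@dataclass
class SyntheticDataset:
    X: ExpressionMatrix
    true_labels: np.ndarray
    config: SyntheticConfig = field(repr=False)


def generate_planted_expression(cfg: SyntheticConfig) -> SyntheticDataset:
    """Draw a planted-cluster expression matrix, reproducible from seed."""
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_cells, cfg.n_genes
    log_x = rng.normal(BASELINE_LOG2_MEAN, cfg.dispersion, size=(n, m))

    labels = np.repeat(np.arange(len(cfg.cluster_sizes)), cfg.cluster_sizes)
    mpc = cfg.markers_per_cluster
    for l, _ in enumerate(cfg.cluster_sizes):
        cells = np.flatnonzero(labels == l)
        genes = np.arange(l * mpc, (l + 1) * mpc)
        log_x[np.ix_(cells, genes)] = rng.normal(
            BASELINE_LOG2_MEAN + cfg.effect, cfg.dispersion, size=(cells.size, mpc)
        )
    values = np.exp2(log_x)
    if cfg.dropout_rate > 0:
        keep = rng.random(size=(n, m)) >= cfg.dropout_rate
        values = values * keep
    X = ExpressionMatrix(
        values=values,
        cell_ids=[f"cell_{i:04d}" for i in range(n)],
        gene_ids=[f"gene_{j:04d}" for j in range(m)],
    )
    return SyntheticDataset(X=X, true_labels=labels, config=cfg)


def _clique_block(c: int) -> np.ndarray:
    W = np.ones((c, c))
    np.fill_diagonal(W, 0.0)
    return W


def generate_toy_graph(kind: str, size, seed: int = 0) -> CellGraph:
    """Deterministic structured fixture graphs for the entropy module.

    kind ∈ {two_cliques, barbell, ring, planted_blocks}.  ``size`` is the
    clique size for two_cliques/barbell, the node count for ring, and a
    sequence of block sizes for planted_blocks (within-block weights ~
    Uniform(0.8, 1.0), between ~ Uniform(0, 0.1), seeded).
    """
    if kind == "two_cliques":
        c = int(size)
        if c < 2:
            raise ConfigError("clique size must be >= 2")
        W = np.zeros((2 * c, 2 * c))
        W[:c, :c] = _clique_block(c)
        W[c:, c:] = _clique_block(c)
    elif kind == "barbell":
        c = int(size)
        if c < 2:
            raise ConfigError("clique size must be >= 2")
        W = np.zeros((2 * c, 2 * c))
        W[:c, :c] = _clique_block(c)
        W[c:, c:] = _clique_block(c)
        W[c - 1, c] = W[c, c - 1] = 1.0  # bridge
    elif kind == "ring":
        n = int(size)
        if n < 3:
            raise ConfigError("ring needs >= 3 nodes")
        W = np.zeros((n, n))
        for i in range(n):
            j = (i + 1) % n
            W[i, j] = W[j, i] = 1.0
    elif kind == "planted_blocks":
        sizes = [int(s) for s in (size if np.iterable(size) else [size])]
        if any(s < 1 for s in sizes):
            raise ConfigError("block sizes must be positive")
        rng = np.random.default_rng(seed)
        n = sum(sizes)
        blocks = np.repeat(np.arange(len(sizes)), sizes)
        U = np.zeros((n, n))
        iu, ju = np.triu_indices(n, k=1)
        same = blocks[iu] == blocks[ju]
        vals = np.where(
            same,
            rng.uniform(0.8, 1.0, size=iu.size),
            rng.uniform(0.0, 0.1, size=iu.size),
        )
        U[iu, ju] = vals
        W = U + U.T
    else:
        raise ConfigError(f"unknown toy graph kind: {kind!r}")
    return CellGraph(node_ids=[f"n{i}" for i in range(W.shape[0])], W=W)
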