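"""Multikernel cell-to-cell similarity learning.

The similarity between cells is not taken from a single fixed metric.
Instead, a bank of Gaussian kernels -- one per (k, sigma) pair, where k is
a neighbourhood size and sigma a bandwidth multiplier -- is combined by an
alternating optimization over three blocks:

* ``S``   an n x n row-stochastic similarity matrix (one row per cell),
* ``L``   an n x C orthonormal rank-enforcing factor that pushes the graph
          Laplacian of ``S`` toward C near-zero eigenvalues (C blocks),
* ``w``   a probability vector of kernel weights.

The objective minimized is::

    sum_l w_l <D_l, S>  +  beta ||S||_F^2
        +  gamma tr(L^T (I - (S + S^T)/2) L)  +  rho sum_l w_l log w_l

subject to each row of S on the probability simplex, L^T L = I_C and w on
the simplex.  ``D_l`` is the distance induced by kernel ``l``.  Each block
update is an exact minimizer of its sub-problem, so the objective is
monotone non-increasing.  Simplex projection of the S rows zeroes most
entries, which is what later makes the cell graph sparse without an
explicit k-nearest-neighbour truncation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field


import numpy as np
import scipy.linalg

from .exceptions import ConfigError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "KernelSet",
    "SimilarityModel",
    "OptimizerConfig",
    "preprocess",
    "pairwise_sq_distances",
    "build_kernels",
    "estimate_num_components",
    "learn_similarity",
    "project_rows_to_simplex",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Nonnegative cells x genes expression matrix with identifiers.

    Rows are cells, columns are genes.  Values must be finite and >= 0.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError("expression matrix must be two-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise InputError("expression matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise InputError("expression matrix contains negative entries")
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.cell_ids) != self.values.shape[0]:
            raise InputError(
                f"{len(self.cell_ids)} cell ids for {self.values.shape[0]} rows"
            )
        if len(self.gene_ids) != self.values.shape[1]:
            raise InputError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[1]} columns"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise InputError("cell ids are not unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InputError("gene ids are not unique")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class KernelSet:
    """Bank of Gaussian kernels and their induced distances.

    ``kernels[l]`` is symmetric nonnegative; ``induced_distances[l]`` is the
    kernel-induced metric d_l(i, j) = K(i,i) + K(j,j) - 2 K(i,j), which is
    >= 0 with a zero diagonal.  ``params[l]`` is the (k, sigma) pair that
    produced kernel ``l``.
    """

    kernels: list[np.ndarray]
    params: list[tuple[int, float]]
    induced_distances: list[np.ndarray]

    def __post_init__(self) -> None:
        if not (len(self.kernels) == len(self.params) == len(self.induced_distances)):
            raise InputError("kernel bank fields have inconsistent lengths")

    @property
    def n_kernels(self) -> int:
        return len(self.kernels)

    @property
    def n_cells(self) -> int:
        return self.kernels[0].shape[0]

    def average_kernel(self) -> np.ndarray:
        return np.mean(self.kernels, axis=0)


@dataclass
class SimilarityModel:
    """Learned similarity: row-stochastic S, kernel weights w, rank dim C."""

    S: np.ndarray
    w: np.ndarray
    C: int
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True


@dataclass
class OptimizerConfig:
    """Knobs of the similarity optimizer.

    The defaults follow the method's "no parameter tuning" stance: a fixed
    grid of 11 neighbourhood sizes anchored at 10 and 5 bandwidth
    multipliers (55 kernels), unit regularization weights, and a
    deterministic initialisation (the seed only matters to downstream
    consumers that subsample).
    """

    k_grid: tuple[int, ...] = tuple(range(10, 31, 2))
    sigma_grid: tuple[float, ...] = (1.0, 1.25, 1.5, 1.75, 2.0)
    beta: float = 1.0
    gamma: float = 1.0
    rho: float = 1.0
    max_iter: int = 30
    tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ConfigError("tol must be > 0")
        if not self.k_grid or not self.sigma_grid:
            raise ConfigError("k_grid and sigma_grid must be non-empty")
        if any(k < 1 for k in self.k_grid):
            raise ConfigError("neighbour counts must be >= 1")
        if any(s <= 0 for s in self.sigma_grid):
            raise ConfigError("bandwidth multipliers must be > 0")
        if min(self.beta, self.gamma, self.rho) < 0:
            raise ConfigError("beta, gamma, rho must be nonnegative")

    def clipped_to(self, n: int) -> "OptimizerConfig":
        """Return a copy whose k_grid entries are clipped below n.

        Duplicate k values after clipping are kept so the kernel count
        |k_grid| x |sigma_grid| is preserved.
        """
        return OptimizerConfig(
            k_grid=tuple(min(k, n - 1) for k in self.k_grid),
            sigma_grid=self.sigma_grid,
            beta=self.beta,
            gamma=self.gamma,
            rho=self.rho,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.seed,
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def preprocess(X: ExpressionMatrix, log_transform: bool = True) -> ExpressionMatrix:
    """Optionally apply the log2(x + 1) variance-stabilising transform.

    No gene filtering is performed; zero-expression genes are retained so
    the marker step sees the full gene set.
    """
    if not log_transform:
        return ExpressionMatrix(X.values.copy(), list(X.cell_ids), list(X.gene_ids))
    return ExpressionMatrix(np.log2(X.values + 1.0), list(X.cell_ids), list(X.gene_ids))


def pairwise_sq_distances(X: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Squared Euclidean distance between every pair of cell rows."""
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    n = V.shape[0]
    if n < 2:
        raise InputError("need at least 2 cells for pairwise distances")
    sq = np.einsum("ij,ij->i", V, V)
    D = sq[:, None] + sq[None, :] - 2.0 * (V @ V.T)
    np.maximum(D, 0.0, out=D)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def build_kernels(D: np.ndarray, cfg: OptimizerConfig) -> KernelSet:
    """Build the Gaussian kernel bank over the (k, sigma) grid.

    ``D`` holds squared distances.  The bandwidth is adaptive per cell
    pair: eps_ij = sigma * (mu_i + mu_j) / 2, where mu_i is the mean
    *distance* (square root of the entries of D) from cell i to its k
    nearest neighbours (self excluded); the kernel is
    K(i, j) = exp(-D(i, j) / (2 eps_ij^2)), symmetrized.  An all-zero
    distance row falls back to the global mean positive distance for mu_i.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-8):
        raise InputError("distance matrix must be square symmetric")
    for k in cfg.k_grid:
        if k >= n:
            raise ConfigError(f"neighbour count k={k} must be < n={n} cells")

    dist = np.sqrt(D)  # mu lives on the distance scale, D on the squared
    off = dist + np.diag(np.full(n, np.inf))  # exclude self from neighbours
    sorted_off = np.sort(off, axis=1)  # ascending, inf last

    positive = dist[dist > 0]
    global_mu = float(positive.mean()) if positive.size else 1.0

    kernels: list[np.ndarray] = []
    params: list[tuple[int, float]] = []
    induced: list[np.ndarray] = []
    for k in cfg.k_grid:
        mu = sorted_off[:, :k].mean(axis=1)
        zero_rows = mu <= 0
        if np.any(zero_rows):
            logger.info(
                "build_kernels: %d all-zero distance rows fall back to "
                "global mean %.4g", int(zero_rows.sum()), global_mu,
            )
            mu = np.where(zero_rows, global_mu, mu)
        for sigma in cfg.sigma_grid:
            eps = sigma * (mu[:, None] + mu[None, :]) / 2.0
            eps = np.where(eps > 0, eps, 1.0)
            K = np.exp(-D / (2.0 * eps**2))
            K = (K + K.T) / 2.0
            diag = np.diag(K)
            d_ind = diag[:, None] + diag[None, :] - 2.0 * K
            np.maximum(d_ind, 0.0, out=d_ind)
            np.fill_diagonal(d_ind, 0.0)
            kernels.append(K)
            params.append((k, float(sigma)))
            induced.append(d_ind)
    return KernelSet(kernels=kernels, params=params, induced_distances=induced)


def estimate_num_components(K_avg: np.ndarray, c_max: int | None = None) -> int:
    """Eigengap estimate of the number of similarity blocks.

    Uses the ascending spectrum of the symmetric normalized Laplacian
    I - Deg^{-1/2} K Deg^{-1/2}: the position c (1-based) of the largest
    gap lambda_{c+1} - lambda_c over c = 1..C_max, C_max = min(n-1, 30).
    A graph with c well-separated blocks has c near-zero eigenvalues
    followed by a jump, so the gap lands at c.
    """
    K = np.asarray(K_avg, dtype=float)
    n = K.shape[0]
    if n < 3:
        return 1
    deg = K.sum(axis=1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    Lsym = np.eye(n) - inv_sqrt[:, None] * K * inv_sqrt[None, :]
    Lsym = (Lsym + Lsym.T) / 2.0
    eigvals = np.sort(scipy.linalg.eigvalsh(Lsym))
    cmax = min(n - 1, 30) if c_max is None else min(c_max, n - 1)
    gaps = eigvals[1 : cmax + 1] - eigvals[:cmax]
    C = int(np.argmax(gaps)) + 1
    logger.info("estimate_num_components: C=%d (gap %.4g)", C, float(gaps[C - 1]))
    return C


def project_rows_to_simplex(V: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row of V onto the probability simplex."""
    n, m = V.shape
    U = np.sort(V, axis=1)[:, ::-1]
    css = np.cumsum(U, axis=1) - 1.0
    idx = np.arange(1, m + 1)
    cond = U - css / idx > 0
    rho = m - np.argmax(cond[:, ::-1], axis=1) - 1  # last True per row
    theta = css[np.arange(n), rho] / (rho + 1)
    return np.maximum(V - theta[:, None], 0.0)


def _objective(
    S: np.ndarray,
    L: np.ndarray,
    w: np.ndarray,
    alignments: np.ndarray,
    beta: float,
    gamma: float,
    rho: float,
) -> float:
    sym = (S + S.T) / 2.0
    lap_term = L.shape[1] - float(np.einsum("ij,ij->", L @ L.T, sym))
    ent = float(np.sum(w * np.log(np.where(w > 0, w, 1.0))))
    return (
        float(w @ alignments)
        + beta * float(np.sum(S * S))
        + gamma * lap_term
        + rho * ent
    )


def _top_eigvecs(A: np.ndarray, C: int) -> np.ndarray:
    n = A.shape[0]
    _, vecs = scipy.linalg.eigh(A, subset_by_index=[n - C, n - 1])
    return vecs


def learn_similarity(
    kernels: KernelSet, C: int, cfg: OptimizerConfig
) -> SimilarityModel:
    """Alternating minimization over S (similarity), L (rank factor), w.

    S-update: per-row quadratic minimized by projecting
    -(sum_l w_l D_l - gamma L L^T) / (2 beta) onto the simplex, with the
    diagonal (self-similarity) forced to zero.  L-update: top-C
    eigenvectors of (S + S^T)/2.  w-update: softmax of the negative
    per-kernel alignment a_l = <D_l, S> scaled by 1/rho.  Stops at
    ``cfg.max_iter`` or when the relative objective change drops below
    ``cfg.tol``; non-convergence returns the last iterate with
    ``converged=False`` rather than raising.
    """
    if C < 1:
        raise ConfigError("C must be >= 1")
    n = kernels.n_cells
    if C >= n:
        raise ConfigError(f"C={C} must be < n={n}")
    D = np.stack(kernels.induced_distances)  # (L, n, n)
    n_k = kernels.n_kernels

    # deterministic init: row-normalised zero-diagonal average kernel
    S = kernels.average_kernel().copy()
    np.fill_diagonal(S, 0.0)
    rowsum = S.sum(axis=1, keepdims=True)
    uniform_row = np.full(n, 1.0 / max(n - 1, 1))
    S = np.where(rowsum > 0, S / np.where(rowsum > 0, rowsum, 1.0), uniform_row)
    np.fill_diagonal(S, 0.0)
    w = np.full(n_k, 1.0 / n_k)
    L = _top_eigvecs((S + S.T) / 2.0, C)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        # S-update (exact per-row simplex-constrained quadratic)
        Dw = np.einsum("l,lij->ij", w, D)
        M = L @ L.T
        V = -(Dw - cfg.gamma * M) / (2.0 * cfg.beta)
        np.fill_diagonal(V, -np.inf)  # no self-similarity
        V = np.where(np.isneginf(V), -1e30, V)
        S = project_rows_to_simplex(V)
        np.fill_diagonal(S, 0.0)

        # L-update
        L = _top_eigvecs((S + S.T) / 2.0, C)

        # w-update: entropic reweighting by per-kernel alignment
        alignments = np.einsum("lij,ij->l", D, S)
        if cfg.rho > 0:
            logits = -alignments / cfg.rho
            logits -= logits.max()
            w = np.exp(logits)
            w /= w.sum()
        else:  # degenerate: all mass on the best-aligned kernel
            w = np.zeros(n_k)
            w[int(np.argmin(alignments))] = 1.0

        obj = _objective(S, L, w, alignments, cfg.beta, cfg.gamma, cfg.rho)
        trace.append(obj)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(prev - obj) <= cfg.tol * max(1.0, abs(prev)):
                converged = True
                break
    if not converged and cfg.max_iter > 1:
        logger.warning(
            "learn_similarity: no convergence in %d iterations "
            "(last rel change %.3g); returning last iterate",
            cfg.max_iter,
            abs(trace[-1] - trace[-2]) / max(1.0, abs(trace[-2]))
            if len(trace) >= 2
            else float("nan"),
        )
    logger.info(
        "learn_similarity: %d iterations, objective %.6g, %d/%d kernels "
        "above 1%% weight",
        it, trace[-1], int(np.sum(w > 0.01)), n_k,
    )
    return SimilarityModel(
        S=S, w=w, C=C, objective_trace=trace, n_iter=it, converged=converged
    )
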