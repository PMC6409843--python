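"""End-to-end orchestration: expression matrix in, communities out.

Stages, in order: optional log2(x+1) preprocessing -> squared-distance
matrix -> Gaussian kernel bank over the (k, sigma) grid -> eigengap
estimate of the rank dimension C (unless overridden) -> multikernel
similarity learning -> weighted cell graph -> greedy structure-entropy
minimization -> per-community marker ranking -> optional NMI/ARI against
supplied true labels.  The cluster count is decided by the entropy
minimization, never supplied by the user.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .entropy import EntropyReport, Partition, minimize_entropy
from .exceptions import InputError
from .graph import build_cell_graph
from .io import read_expression, read_labels, write_outputs
from .markers_metrics import MarkerGeneTable, ari, nmi, rank_marker_genes
from .similarity import (
    ExpressionMatrix,
    OptimizerConfig,
    SimilarityModel,
    build_kernels,
    estimate_num_components,
    learn_similarity,
    pairwise_sq_distances,
    preprocess,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ClusterResult", "cluster_cells", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a full run needs, from file paths to optimizer knobs."""

    input_path: str | Path
    format: str | None = None  # inferred from suffix when None
    orientation: str = "cells_by_genes"
    log_transform: bool = True
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    c_override: int | None = None
    knn_truncate: int | None = None
    entropy_tol: float = 1e-12
    top_k_markers: int = 10
    labels_path: str | Path | None = None
    outdir: str | Path | None = None
    seed: int = 0


@dataclass
class ClusterResult:
    """Partition, entropy decomposition, markers, metrics and run metadata."""

    cell_ids: list[str]
    partition: Partition
    entropy: EntropyReport
    similarity: SimilarityModel
    markers: MarkerGeneTable
    metrics: dict | None
    run_meta: dict

    @property
    def n_communities(self) -> int:
        return self.partition.num_communities


def cluster_cells(
    X: ExpressionMatrix,
    optimizer: OptimizerConfig | None = None,
    log_transform: bool = True,
    c_override: int | None = None,
    knn_truncate: int | None = None,
    entropy_tol: float = 1e-12,
    top_k_markers: int = 10,
    true_labels=None,
) -> ClusterResult:
    """Run the full method on an in-memory expression matrix.

    ``true_labels`` (one label per cell, any hashable values) switches on
    NMI/ARI evaluation.  Deterministic for a fixed input and configuration.
    """
    cfg = (optimizer or OptimizerConfig()).clipped_to(X.n_cells)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    Xp = preprocess(X, log_transform=log_transform)
    D = pairwise_sq_distances(Xp)
    kernels = build_kernels(D, cfg)
    timings["kernels_s"] = time.perf_counter() - t0
    logger.info(
        "pipeline: %d cells x %d genes, %d kernels",
        X.n_cells, X.n_genes, kernels.n_kernels,
    )

    t0 = time.perf_counter()
    if c_override is not None:
        C = int(c_override)
    else:
        C = estimate_num_components(kernels.average_kernel())
    model = learn_similarity(kernels, C, cfg)
    timings["similarity_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    G = build_cell_graph(model, node_ids=X.cell_ids, knn_truncate=knn_truncate)
    partition, report = minimize_entropy(G, tol=entropy_tol)
    timings["clustering_s"] = time.perf_counter() - t0
    logger.info(
        "pipeline: %d communities, H^P = %.4f bits",
        partition.num_communities, report.total_bits,
    )

    markers = rank_marker_genes(X, partition, top_k=top_k_markers)

    metrics = None
    if true_labels is not None:
        true_labels = list(true_labels)
        if len(true_labels) != X.n_cells:
            raise InputError(
                f"{len(true_labels)} true labels for {X.n_cells} cells"
            )
        metrics = {
            "nmi": nmi(true_labels, partition.labels),
            "ari": ari(true_labels, partition.labels),
            "n_clusters_pred": partition.num_communities,
            "n_clusters_true": len(set(true_labels)),
        }
        logger.info("pipeline: NMI=%.4f ARI=%.4f", metrics["nmi"], metrics["ari"])

    run_meta = {
        "version": __version__,
        "n_cells": X.n_cells,
        "n_genes": X.n_genes,
        "log_transform": log_transform,
        "k_grid": list(cfg.k_grid),
        "sigma_grid": list(cfg.sigma_grid),
        "beta": cfg.beta,
        "gamma": cfg.gamma,
        "rho": cfg.rho,
        "C": model.C,
        "c_overridden": c_override is not None,
        "n_iterations": model.n_iter,
        "converged": model.converged,
        "n_communities": partition.num_communities,
        "entropy_bits": report.total_bits,
        "timings": {k: round(v, 4) for k, v in timings.items()},
    }
    return ClusterResult(
        cell_ids=list(X.cell_ids),
        partition=partition,
        entropy=report,
        similarity=model,
        markers=markers,
        metrics=metrics,
        run_meta=run_meta,
    )


def run_pipeline(cfg: PipelineConfig) -> ClusterResult:
    """File-based front end: read, cluster, optionally score and write."""
    X = read_expression(cfg.input_path, format=cfg.format, orientation=cfg.orientation)
    true_labels = None
    if cfg.labels_path is not None:
        mapping = read_labels(cfg.labels_path)
        missing = [c for c in X.cell_ids if c not in mapping]
        if missing:
            raise InputError(
                f"labels file is missing {len(missing)} cell ids "
                f"(first: {missing[0]!r})"
            )
        true_labels = [mapping[c] for c in X.cell_ids]
    result = cluster_cells(
        X,
        optimizer=cfg.optimizer,
        log_transform=cfg.log_transform,
        c_override=cfg.c_override,
        knn_truncate=cfg.knn_truncate,
        entropy_tol=cfg.entropy_tol,
        top_k_markers=cfg.top_k_markers,
        true_labels=true_labels,
    )
    result.run_meta["input_path"] = str(cfg.input_path)
    result.run_meta["seed"] = cfg.seed
    if cfg.outdir is not None:
        write_outputs(result, cfg.outdir)
    return result
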