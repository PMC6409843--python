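"""Readers and writers for expression matrices, labels and run outputs.

Supported matrix formats: CSV/TSV with a header row of gene ids and a
first column of cell ids, and Matrix Market (MTX) coordinate triplets with
optional companion id files ``<stem>_rows.tsv`` / ``<stem>_cols.tsv`` (one
id per line).  The canonical in-memory orientation is cells x genes; MTX
deposits are commonly genes x cells, so an orientation flag transposes on
read.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .exceptions import InputError, ParseError
from .similarity import ExpressionMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import ClusterResult

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "write_edge_list",
    "write_outputs",
]

_FORMATS = ("csv", "tsv", "mtx")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    raise InputError(
        f"cannot infer format from {path.name!r}; pass format= explicitly"
    )


def _companion_ids(path: Path, which: str, count: int) -> list[str] | None:
    side = path.with_name(path.stem + f"_{which}.tsv")
    if not side.exists():
        return None
    ids = [line.strip() for line in side.read_text().splitlines() if line.strip()]
    if len(ids) != count:
        raise ParseError(
            f"{side.name}: {len(ids)} ids for {count} {which} (line count mismatch)"
        )
    return ids


def read_expression(
    path, format: str | None = None, orientation: str = "cells_by_genes"
) -> ExpressionMatrix:
    """Read an expression matrix into the canonical cells x genes layout.

    ``orientation="genes_by_cells"`` transposes after reading (the common
    MTX deposit convention).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise InputError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise InputError(f"unknown orientation {orientation!r}")

    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pandas raises many flavours
            raise ParseError(f"{path.name}: {exc}") from exc
        bad = df.columns[~df.apply(
            lambda col: pd.to_numeric(col, errors="coerce").notna().all()
        )]
        if len(bad):
            raise ParseError(
                f"{path.name}: non-numeric values in column(s) {list(bad)[:3]}"
            )
        values = df.to_numpy(dtype=float)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
    else:  # mtx
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ParseError(f"{path.name}: {exc}") from exc
        values = np.asarray(
            mat.toarray() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        row_ids = _companion_ids(path, "rows", values.shape[0]) or [
            f"row_{i}" for i in range(values.shape[0])
        ]
        col_ids = _companion_ids(path, "cols", values.shape[1]) or [
            f"col_{j}" for j in range(values.shape[1])
        ]

    if orientation == "genes_by_cells":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    logger.info(
        "read_expression: %s -> %d cells x %d genes", path.name, *values.shape
    )
    return ExpressionMatrix(values=values, cell_ids=row_ids, gene_ids=col_ids)


def write_expression(
    X: ExpressionMatrix, path, format: str | None = None
) -> Path:
    """Write cells x genes to CSV/TSV (dense) or MTX (+ companion id files)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        pd.DataFrame(X.values, index=X.cell_ids, columns=X.gene_ids).to_csv(
            path, sep=sep
        )
    elif fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(X.values))
        path.with_name(path.stem + "_rows.tsv").write_text(
            "\n".join(X.cell_ids) + "\n"
        )
        path.with_name(path.stem + "_cols.tsv").write_text(
            "\n".join(X.gene_ids) + "\n"
        )
    else:
        raise InputError(f"unknown format {fmt!r}")
    return path


def read_labels(path) -> dict[str, str]:
    """Read a two-column TSV (cell_id, label) into an ordered mapping."""
    path = Path(path)
    labels: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(
                f"{path.name}:{lineno}: expected 2 tab-separated fields, "
                f"got {len(parts)}"
            )
        cell, lab = parts
        if cell == "cell_id" and lineno == 1:  # optional header
            continue
        if cell in labels:
            raise ParseError(f"{path.name}:{lineno}: duplicate cell id {cell!r}")
        labels[cell] = lab
    return labels


def write_labels(labels: dict[str, str], path) -> Path:
    path = Path(path)
    lines = ["cell_id\tlabel"] + [f"{c}\t{l}" for c, l in labels.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_edge_list(graph, path) -> Path:
    """Write a cell graph as a TSV edge list (cell_a, cell_b, weight)."""
    path = Path(path)
    lines = ["cell_a\tcell_b\tweight"] + [
        f"{a}\t{b}\t{w:.10g}" for a, b, w in graph.edge_list()
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_outputs(result: "ClusterResult", outdir) -> list[Path]:
    """Write clusters.tsv, markers.tsv, entropy.json, metrics.json (if
    labels were supplied) and run_meta.json; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    clusters = outdir / "clusters.tsv"
    lines = ["cell_id\tcommunity"] + [
        f"{cid}\t{lab}"
        for cid, lab in zip(result.cell_ids, result.partition.labels)
    ]
    clusters.write_text("\n".join(lines) + "\n")
    written.append(clusters)

    markers = outdir / "markers.tsv"
    rows = ["community\trank\tgene_id\tmean_expression"] + [
        f"{l}\t{r}\t{g}\t{m:.10g}" for (l, r, g, m) in result.markers.to_rows()
    ]
    markers.write_text("\n".join(rows) + "\n")
    written.append(markers)

    entropy_path = outdir / "entropy.json"
    entropy_path.write_text(
        json.dumps(result.entropy.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    written.append(entropy_path)

    if result.metrics is not None:
        metrics_path = outdir / "metrics.json"
        metrics_path.write_text(
            json.dumps(result.metrics, indent=2, sort_keys=True) + "\n"
        )
        written.append(metrics_path)

    meta_path = outdir / "run_meta.json"
    meta_path.write_text(
        json.dumps(result.run_meta, indent=2, sort_keys=True) + "\n"
    )
    written.append(meta_path)
    logger.info("write_outputs: wrote %d files to %s", len(written), outdir)
    return written
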