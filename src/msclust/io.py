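"""Readers and writers for the tool's file surface.

Supported inputs: 10x-style MatrixMarket triplet directories (matrix.mtx +
barcodes.tsv + features.tsv/genes.tsv, orientation auto-detected from the
id counts), dense expression TSV (genes as rows, cells as columns),
reduced-coordinate TSV (cells as rows), precomputed similarity TSV, and
long-format (cell, cluster) label TSVs.  All outputs are plain text.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .similarity import ExpressionMatrix, SimilarityMatrix

__all__ = [
    "read_input",
    "read_mtx_dir",
    "read_dense_tsv",
    "read_coords_tsv",
    "read_similarity_tsv",
    "read_labels_tsv",
    "write_edge_list",
    "read_edge_list",
    "write_dataset_tsv",
]

FORMATS = ("mtx_dir", "tsv_dense", "tsv_coords", "tsv_similarity")


def read_input(path, fmt: str, require_nonnegative: bool = True):
    """Dispatch on format; returns ExpressionMatrix, (coords, ids) or
    SimilarityMatrix."""
    if fmt not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}, got {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if fmt == "mtx_dir":
        return read_mtx_dir(path, require_nonnegative=require_nonnegative)
    if fmt == "tsv_dense":
        return read_dense_tsv(path, require_nonnegative=require_nonnegative)
    if fmt == "tsv_coords":
        return read_coords_tsv(path)
    return read_similarity_tsv(path)


def _check_nonnegative(values: np.ndarray, source: str) -> None:
    if (values < 0).any():
        raise ValueError(
            f"negative expression values in {source}; counts must be >= 0 "
            "(pass require_nonnegative=False / --allow-negative for centered data)"
        )


def read_mtx_dir(path, require_nonnegative: bool = True) -> ExpressionMatrix:
    """Read a 10x-style triplet directory into a cells x genes matrix."""
    from scipy.io import mmread

    path = Path(path)
    mtx_file = path / "matrix.mtx"
    if not mtx_file.exists():
        raise FileNotFoundError(f"missing matrix file: {mtx_file}")
    barcodes_file = path / "barcodes.tsv"
    if not barcodes_file.exists():
        raise FileNotFoundError(f"missing barcodes file: {barcodes_file}")
    features_file = path / "features.tsv"
    if not features_file.exists():
        features_file = path / "genes.tsv"
    if not features_file.exists():
        raise FileNotFoundError(f"missing features file: {path / 'features.tsv'}")

    mat = np.asarray(mmread(str(mtx_file)).todense(), dtype=float)
    barcodes = [l.split("\t")[0] for l in barcodes_file.read_text().splitlines() if l]
    features = [l.split("\t")[0] for l in features_file.read_text().splitlines() if l]

    if mat.shape == (len(features), len(barcodes)):
        mat = mat.T  # genes x cells on disk -> cells x genes in memory
    elif mat.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix shape {mat.shape} matches neither "
            f"{len(features)} features x {len(barcodes)} barcodes nor its transpose"
        )
    if require_nonnegative:
        _check_nonnegative(mat, str(mtx_file))
    return ExpressionMatrix(values=mat, cell_ids=barcodes, gene_ids=features)


def read_dense_tsv(path, require_nonnegative: bool = True) -> ExpressionMatrix:
    """Dense TSV with genes/features as rows and cells as columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"ragged or missing values in {path}")
    values = df.to_numpy(dtype=float).T
    if require_nonnegative:
        _check_nonnegative(values, str(path))
    return ExpressionMatrix(
        values=values,
        cell_ids=[str(c) for c in df.columns],
        gene_ids=[str(g) for g in df.index],
    )


def read_coords_tsv(path) -> tuple[np.ndarray, list[str]]:
    """Cells x components coordinate TSV (cells as rows)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"missing values in coordinates {path}")
    return df.to_numpy(dtype=float), [str(c) for c in df.index]


def read_similarity_tsv(path) -> SimilarityMatrix:
    """Precomputed similarity TSV with matching header row/column of ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("similarity TSV row and column ids differ")
    vals = df.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T, atol=1e-8):
        raise ValueError("similarity matrix is asymmetric beyond 1e-8")
    vals = (vals + vals.T) / 2.0
    mode = "correlation" if np.abs(vals).max() <= 1.0 + 1e-12 else "neg_euclidean"
    return SimilarityMatrix(
        values=vals, cell_ids=[str(c) for c in df.columns], mode=mode
    )


def read_labels_tsv(path) -> dict[str, str]:
    """Long-format TSV (cell_id, cluster_id), with or without header."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs >= 2 columns")
    if df.iloc[0, 0].lower() in ("cell", "cell_id", "barcode", "sample"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_edge_list(g: nx.Graph, path) -> None:
    """3-column weighted edge list using cell id strings."""
    ids = g.graph.get("cell_ids")
    rows = []
    for u, v, d in sorted(g.edges(data=True)):
        cu = ids[u] if ids is not None else str(u)
        cv = ids[v] if ids is not None else str(v)
        rows.append(f"{cu}\t{cv}\t{d['weight']:.10g}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_edge_list(path) -> nx.Graph:
    g = nx.Graph()
    ids: list[str] = []
    index: dict[str, int] = {}
    edges = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        u, v, w = line.split("\t")
        for c in (u, v):
            if c not in index:
                index[c] = len(ids)
                ids.append(c)
        edges.append((index[u], index[v], float(w)))
    g.add_nodes_from(range(len(ids)))
    g.add_weighted_edges_from(edges)
    g.graph["cell_ids"] = ids
    return g


def write_dataset_tsv(dataset, prefix) -> tuple[Path, Path]:
    """Write PREFIX.data.tsv (features x samples) and PREFIX.labels.tsv."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    data_path = prefix.with_suffix(prefix.suffix + ".data.tsv")
    labels_path = prefix.with_suffix(prefix.suffix + ".labels.tsv")
    feat_ids = [f"F{i + 1:04d}" for i in range(dataset.data.shape[0])]
    df = pd.DataFrame(dataset.data, index=feat_ids, columns=dataset.sample_ids)
    df.to_csv(data_path, sep="\t", float_format="%.8g")
    lab = pd.DataFrame(
        {
            "sample": dataset.sample_ids,
            "inner_label": dataset.labels_inner,
            "outer_label": (
                dataset.labels_outer
                if dataset.labels_outer is not None
                else ["NA"] * len(dataset.sample_ids)
            ),
        }
    )
    lab.to_csv(labels_path, sep="\t", index=False)
    return data_path, labels_path


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
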