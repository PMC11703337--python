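"""Cell-cell similarity and the expressed-gene Jaccard index.

Two similarity modes feed the network construction: Pearson correlation of
expression profiles over a (possibly masked) feature set, and negated
Euclidean distance between reduced-dimension coordinates.  Both are stored
so that larger values always mean "more similar".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "SimilarityMatrix",
    "pearson_similarity",
    "euclidean_similarity",
    "expressed_jaccard",
    "top_variance_mask",
]


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values.

    ``feature_mask`` optionally restricts similarity computations to a gene
    subset (boolean array over genes).  Nonnegativity is a property of count
    data and is enforced by the file readers, not by this container, so that
    centered/simulated data can flow through the same pipeline.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    feature_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-dimensional")
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n_cells} rows")
        if len(self.gene_ids) != n_genes:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n_genes} columns")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")
        if self.feature_mask is not None:
            self.feature_mask = np.asarray(self.feature_mask, dtype=bool)
            if self.feature_mask.shape != (n_genes,):
                raise ValueError("feature_mask must be a boolean vector over genes")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def masked_values(self) -> np.ndarray:
        if self.feature_mask is None:
            return self.values
        return self.values[:, self.feature_mask]


@dataclass
class SimilarityMatrix:
    """Symmetric cells x cells similarity; higher is always more similar."""

    values: np.ndarray
    cell_ids: list[str]
    mode: str  # "correlation" | "neg_euclidean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.cell_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match cell ids")
        if self.mode not in ("correlation", "neg_euclidean"):
            raise ValueError(f"unknown similarity mode {self.mode!r}")
        if not np.isfinite(self.values).all():
            raise ValueError("similarity values must be finite")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("similarity matrix must be symmetric")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def pearson_similarity(expr: ExpressionMatrix) -> SimilarityMatrix:
    """Pearson correlation between cells over the masked features."""
    vals = expr.masked_values()
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 features to correlate cells")
    sd = vals.std(axis=1)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        bad = [expr.cell_ids[i] for i in zero_var]
        raise ValueError(f"zero-variance cells, correlation undefined: {bad}")
    sim = np.corrcoef(vals)
    np.fill_diagonal(sim, 1.0)
    sim = np.clip(sim, -1.0, 1.0)
    # force exact symmetry against floating-point asymmetry in BLAS paths
    sim = (sim + sim.T) / 2.0
    return SimilarityMatrix(values=sim, cell_ids=list(expr.cell_ids), mode="correlation")


def euclidean_similarity(coords: np.ndarray, cell_ids: Sequence[str]) -> SimilarityMatrix:
    """Negated Euclidean distance between coordinate rows (e.g. PCs)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] < 2:
        raise ValueError("coordinates must be cells x components with >= 2 components")
    if not np.isfinite(coords).all():
        raise ValueError("coordinates contain NaN or infinite values")
    from scipy.spatial.distance import squareform, pdist

    dist = squareform(pdist(coords, metric="euclidean"))
    return SimilarityMatrix(values=-dist, cell_ids=list(cell_ids), mode="neg_euclidean")


def expressed_jaccard(expr: ExpressionMatrix, i: int, j: int) -> float:
    """Jaccard index of the expressed-gene sets (value > 0) of two cells."""
    ei = expr.values[i] > 0
    ej = expr.values[j] > 0
    union = np.count_nonzero(ei | ej)
    if union == 0:
        return 0.0
    return float(np.count_nonzero(ei & ej) / union)


def expressed_jaccard_edges(expr: ExpressionMatrix, pairs: np.ndarray) -> np.ndarray:
    """Vectorized expressed-gene Jaccard for an array of (i, j) index pairs."""
    expressed = expr.values > 0
    pairs = np.asarray(pairs)
    a = expressed[pairs[:, 0]]
    b = expressed[pairs[:, 1]]
    inter = np.count_nonzero(a & b, axis=1).astype(float)
    union = np.count_nonzero(a | b, axis=1).astype(float)
    out = np.zeros(len(pairs))
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out


def top_variance_mask(expr: ExpressionMatrix, n_top: int = 2000) -> np.ndarray:
    """Boolean mask selecting the ``n_top`` highest-variance genes.

    Plumbing fallback for when no externally selected variable-feature list
    is supplied; ties broken by gene order.
    """
    var = expr.values.var(axis=0)
    n_top = min(n_top, var.size)
    order = np.argsort(-var, kind="stable")[:n_top]
    mask = np.zeros(var.size, dtype=bool)
    mask[order] = True
    return mask
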