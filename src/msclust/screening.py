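"""Low-quality edge screens applied to the raw LEN.

Two post-hoc filters yield the final cell network G_o:

* a low-similarity screen that models similarity as a smooth (LOESS)
  function of the expressed-gene Jaccard index between the two cells and
  drops edges falling more than two residual standard deviations below the
  fitted mean — removing links whose low correlation is not explained by
  transcriptome sparsity; and
* a low-centrality screen that contests the lowest-similarity quantile of
  edges and removes an edge when doing so raises the endpoints' mutual
  neighbor ratio, a second-order measure of local clustering.

Both screens only delete edges; nodes and surviving weights are untouched.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np

from .similarity import ExpressionMatrix, expressed_jaccard_edges

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeScreenReport",
    "low_similarity_screen",
    "mutual_neighbor_ratio",
    "centrality_screen",
    "screen_graph",
]

MIN_EDGES_FOR_LOESS = 30


@dataclass
class EdgeScreenReport:
    n_edges_in: int = 0
    n_removed_similarity: int = 0
    n_removed_centrality: int = 0
    contested_quantile: float = 0.25
    similarity_screen_skipped: bool = False
    skip_reason: Optional[str] = None
    n_components_out: int = 0
    loess_fit: Optional[dict] = None

    @property
    def n_edges_out(self) -> int:
        return self.n_edges_in - self.n_removed_similarity - self.n_removed_centrality

    def to_dict(self) -> dict:
        return {
            "n_edges_in": self.n_edges_in,
            "n_removed_similarity": self.n_removed_similarity,
            "n_removed_centrality": self.n_removed_centrality,
            "n_edges_out": self.n_edges_out,
            "contested_quantile": self.contested_quantile,
            "similarity_screen_skipped": self.similarity_screen_skipped,
            "skip_reason": self.skip_reason,
            "n_components_out": self.n_components_out,
        }


def low_similarity_screen(
    g: nx.Graph,
    expr: Optional[ExpressionMatrix],
    span: float = 0.5,
    n_sd: float = 2.0,
    report: Optional[EdgeScreenReport] = None,
) -> nx.Graph:
    """Drop edges whose similarity falls > n_sd residual SDs below the
    LOESS fit of similarity against the expressed-gene Jaccard index.

    Applies only to correlation-mode graphs (the Jaccard index lives in
    expression space); otherwise, or with too few edges or constant Jaccard,
    the graph passes through unchanged with a logged warning.
    """
    if g.graph.get("stage") != "raw_union":
        raise ValueError("low_similarity_screen expects a raw_union-stage graph")
    out = g.copy()
    out.graph["stage"] = "similarity_screened"
    if report is None:
        report = EdgeScreenReport()
    report.n_edges_in = g.number_of_edges()

    def _skip(reason: str) -> nx.Graph:
        report.similarity_screen_skipped = True
        report.skip_reason = reason
        logger.warning("low-similarity screen skipped: %s", reason)
        return out

    if g.graph.get("mode") != "correlation":
        return _skip(f"similarity mode {g.graph.get('mode')!r} is not correlation")
    if expr is None:
        return _skip("no expression matrix supplied")
    if g.number_of_edges() < MIN_EDGES_FOR_LOESS:
        return _skip(f"only {g.number_of_edges()} edges (< {MIN_EDGES_FOR_LOESS})")

    edges = np.array([(u, v) for u, v in g.edges()])
    s = np.array([g[u][v]["weight"] for u, v in edges])
    j = expressed_jaccard_edges(expr, edges)
    if np.ptp(j) == 0:
        return _skip("expressed-gene Jaccard is constant across edges")

    fitted = _smooth_fit(j, s, span)
    resid = s - fitted
    sd = float(resid.std(ddof=1))
    report.loess_fit = {"residual_sd": sd, "span": span}
    if sd <= 1e-10 * max(1.0, float(np.abs(s).max())):
        return out  # numerically exact fit: nothing is an outlier
    drop = resid < -n_sd * sd
    for (u, v) in edges[drop]:
        out.remove_edge(int(u), int(v))
    report.n_removed_similarity = int(drop.sum())
    return out


def _smooth_fit(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """LOESS fit of y on x, with a linear fallback if ill-conditioned."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitted = lowess(y, x, frac=span, return_sorted=False)
    if not np.isfinite(fitted).all():
        coef = np.polyfit(x, y, deg=1)
        fitted = np.polyval(coef, x)
    return np.asarray(fitted, dtype=float)


def mutual_neighbor_ratio(g: nx.Graph, i: int, j: int) -> float:
    """Jaccard index of the open neighborhoods of i and j in g."""
    if i not in g or j not in g:
        raise ValueError(f"nodes {i}, {j} must be present in the graph")
    ni = set(g.neighbors(i))
    nj = set(g.neighbors(j))
    union = ni | nj
    if not union:
        return 0.0
    return len(ni & nj) / len(union)


def centrality_screen(
    g: nx.Graph,
    contested_quantile: float = 0.25,
    report: Optional[EdgeScreenReport] = None,
) -> nx.Graph:
    """Contest the lowest-similarity quantile of edges for removal.

    Edges are visited in ascending similarity; an edge is removed iff the
    mutual neighbor ratio of its endpoints strictly improves without it and
    neither endpoint would be orphaned.  Removals take effect immediately,
    so later decisions see the updated graph.
    """
    if g.graph.get("stage") != "similarity_screened":
        raise ValueError("centrality_screen expects a similarity_screened-stage graph")
    if not (0.0 <= contested_quantile <= 1.0):
        raise ValueError("contested_quantile must be in [0, 1]")
    out = g.copy()
    out.graph["stage"] = "final"
    if report is None:
        report = EdgeScreenReport()
    report.contested_quantile = contested_quantile

    m = out.number_of_edges()
    n_contest = int(np.floor(contested_quantile * m))
    if n_contest == 0:
        return out
    # ascending similarity, deterministic tie-break on indices
    ranked = sorted(
        ((d["weight"], min(u, v), max(u, v)) for u, v, d in out.edges(data=True))
    )
    removed = 0
    for w, u, v in ranked[:n_contest]:
        if not out.has_edge(u, v):
            continue
        if out.degree(u) <= 1 or out.degree(v) <= 1:
            continue
        m_with = mutual_neighbor_ratio(out, u, v)
        out.remove_edge(u, v)
        m_without = mutual_neighbor_ratio(out, u, v)
        if m_without > m_with:
            removed += 1
        else:
            out.add_edge(u, v, weight=w)
    report.n_removed_centrality = removed
    return out


def screen_graph(
    g: nx.Graph,
    expr: Optional[ExpressionMatrix] = None,
    contested_quantile: float = 0.25,
    span: float = 0.5,
    skip_similarity: bool = False,
) -> tuple[nx.Graph, EdgeScreenReport]:
    """Run both screens and return the final graph G_o plus a report."""
    report = EdgeScreenReport()
    if skip_similarity:
        report.n_edges_in = g.number_of_edges()
        report.similarity_screen_skipped = True
        report.skip_reason = "disabled by caller"
        mid = g.copy()
        mid.graph["stage"] = "similarity_screened"
    else:
        mid = low_similarity_screen(g, expr, span=span, report=report)
    final = centrality_screen(mid, contested_quantile=contested_quantile, report=report)
    report.n_components_out = nx.number_connected_components(final)
    return final, report
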