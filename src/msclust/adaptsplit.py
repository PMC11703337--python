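"""AdaptSplit: resolution scanning and stability-breakpoint selection.

One split step runs Leiden community detection under the
Reichardt-Bornholdt configuration objective over a grid of resolutions
gamma in (0, 2], records the intra-cluster link count K_in at each gamma,
fits a piecewise-constant step model of K_in versus gamma, and returns the
clustering at the median gamma of the first (lowest-gamma) stable regime —
the coarsest stable solution, whose clusters are split further by the
hierarchy driver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import igraph as ig
import leidenalg as la
import networkx as nx
import numpy as np

__all__ = [
    "GammaScan",
    "default_gamma_grid",
    "scan_resolutions",
    "intra_cluster_links",
    "detect_first_breakpoint",
    "adapt_split",
    "AdaptSplitResult",
]

# split kept iff it removes >= this fraction of the root sum of squares
STEP_MIN_GAIN = 0.25
STEP_MIN_LEAF = 2


def default_gamma_grid(step: float = 0.05, gamma_max: float = 2.0) -> np.ndarray:
    """Resolution grid {step, 2*step, ..., gamma_max}."""
    n = int(round(gamma_max / step))
    return np.round(np.arange(1, n + 1) * step, 10)


@dataclass
class GammaScan:
    """Per-resolution clustering solutions of one parent graph."""

    gammas: np.ndarray
    clusterings: list[list[set]]
    kin: np.ndarray
    n_clusters: np.ndarray


def _to_igraph(g: nx.Graph) -> tuple[ig.Graph, list]:
    nodes = sorted(g.nodes())
    index = {v: k for k, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges()]
    h = ig.Graph(n=len(nodes), edges=edges)
    return h, nodes


def scan_resolutions(
    g: nx.Graph,
    grid: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> GammaScan:
    """Leiden partitions and K_in across the resolution grid.

    Callers normally pass a connected graph (the hierarchy driver splits
    components first); disconnected input is handled, since modularity
    never merges disconnected components.  Clustering is on the unweighted
    topology: K_in counts binary adjacencies, and correlation weights may
    be negative, which modularity does not admit.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot scan an empty graph")
    grid = default_gamma_grid() if grid is None else np.asarray(grid, dtype=float)
    if len(grid) < 5:
        raise ValueError("resolution grid needs at least 5 points")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("resolution grid must be strictly increasing")
    if grid.min() <= 0 or grid.max() > 2.0:
        raise ValueError("resolution grid must lie in (0, 2]")

    h, nodes = _to_igraph(g)
    clusterings: list[list[set]] = []
    kin = np.empty(len(grid), dtype=float)
    n_clusters = np.empty(len(grid), dtype=int)
    for t, gamma in enumerate(grid):
        part = la.find_partition(
            h,
            la.RBConfigurationVertexPartition,
            resolution_parameter=float(gamma),
            seed=seed,
            n_iterations=-1,
        )
        clusters = [set(nodes[i] for i in comm) for comm in part]
        clusterings.append(clusters)
        kin[t] = intra_cluster_links(g, clusters)
        n_clusters[t] = len(clusters)
    return GammaScan(
        gammas=np.asarray(grid, dtype=float),
        clusterings=clusterings,
        kin=kin,
        n_clusters=n_clusters,
    )


def intra_cluster_links(g: nx.Graph, partition: Sequence[set]) -> int:
    """K_in: number of edges whose endpoints share a cluster."""
    assign: dict = {}
    for c, members in enumerate(partition):
        for v in members:
            assign[v] = c
    missing = [v for v in g.nodes() if v not in assign]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    return sum(1 for u, v in g.edges() if assign[u] == assign[v])


def _sse(y: np.ndarray) -> float:
    return float(((y - y.mean()) ** 2).sum())


def _step_split_indices(
    y: np.ndarray,
    min_leaf: int = STEP_MIN_LEAF,
    min_gain: float = STEP_MIN_GAIN,
) -> list[int]:
    """Recursive binary split points of a 1-D sequence (CART-style).

    Returns sorted indices s such that [lo, s) and [s, hi) are separate
    leaves.  A split is kept iff its SSE reduction is at least ``min_gain``
    of the root SSE, making the fit invariant to affine rescaling of y.
    """
    y = np.asarray(y, dtype=float)
    total = _sse(y)
    if total <= 0:
        return []
    splits: list[int] = []

    def rec(lo: int, hi: int) -> None:
        seg = y[lo:hi]
        if len(seg) < 2 * min_leaf:
            return
        parent = _sse(seg)
        best_s, best = None, np.inf
        for s in range(min_leaf, len(seg) - min_leaf + 1):
            cur = _sse(seg[:s]) + _sse(seg[s:])
            if cur < best:
                best, best_s = cur, s
        if best_s is None or (parent - best) / total < min_gain:
            return
        splits.append(lo + best_s)
        rec(lo, lo + best_s)
        rec(lo + best_s, hi)

    rec(0, len(y))
    return sorted(splits)


def detect_first_breakpoint(scan: GammaScan) -> tuple[float, np.ndarray]:
    """First stability breakpoint gamma' and the indices of the first regime.

    If no split survives pruning, the whole grid is the first regime and
    gamma' is the largest grid value.
    """
    if len(scan.gammas) < 5:
        raise ValueError("need at least 5 grid points")
    splits = _step_split_indices(scan.kin)
    if not splits:
        return float(scan.gammas[-1]), np.arange(len(scan.gammas))
    s = splits[0]
    gamma_prime = float((scan.gammas[s - 1] + scan.gammas[s]) / 2.0)
    return gamma_prime, np.arange(s)


@dataclass
class AdaptSplitResult:
    partition: list[set]
    gamma_f: float
    gamma_prime: float
    scan: GammaScan
    no_split: bool

    @property
    def n_clusters(self) -> int:
        return len(self.partition)


def _lower_median(values: np.ndarray) -> float:
    return float(np.sort(values)[(len(values) - 1) // 2])


def adapt_split(
    g: nx.Graph,
    grid: Optional[Sequence[float]] = None,
    seed: int = 0,
    skip_trivial_regime: bool = True,
) -> AdaptSplitResult:
    """One adaptive split: clustering at the median gamma of the first
    stable regime.

    When the first regime's solution is the trivial whole-graph cluster
    (possible at the bottom of the grid), subsequent regimes are consulted
    before declaring that no meaningful split exists; an all-singleton or
    single-cluster final solution sets ``no_split``.
    """
    scan = scan_resolutions(g, grid=grid, seed=seed)
    gamma_prime, _ = detect_first_breakpoint(scan)
    splits = _step_split_indices(scan.kin)
    bounds = [0] + splits + [len(scan.gammas)]
    regimes = [np.arange(bounds[r], bounds[r + 1]) for r in range(len(bounds) - 1)]

    chosen = regimes[0]
    if skip_trivial_regime:
        for regime in regimes:
            gf = _lower_median(scan.gammas[regime])
            idx = int(np.flatnonzero(scan.gammas == gf)[0])
            if len(scan.clusterings[idx]) > 1:
                chosen = regime
                break
        else:
            chosen = regimes[0]

    gamma_f = _lower_median(scan.gammas[chosen])
    idx = int(np.flatnonzero(scan.gammas == gamma_f)[0])
    partition = scan.clusterings[idx]
    n = g.number_of_nodes()
    no_split = len(partition) <= 1 or len(partition) == n
    return AdaptSplitResult(
        partition=partition,
        gamma_f=gamma_f,
        gamma_prime=gamma_prime,
        scan=scan,
        no_split=no_split,
    )
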