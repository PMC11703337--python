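"""Iterative top-down clustering and the multi-scale cluster hierarchy.

Starting from the connected components of the screened cell network G_o,
each sufficiently large cluster is split by AdaptSplit; a candidate child
is accepted only when it is (a) large enough, (b) more compact than its
parent under the calibrated compactness v(alpha) = mean-shortest-path /
(ln N)^alpha, and (c) significantly coherent by a permutation test on its
intra-cluster connectivity lambda.  Accepted children are split
recursively; the result is a rooted hierarchy of nested, overlapping
parent/child cell clusters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from ._seeds import stage_seed
from .adaptsplit import adapt_split

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterNode",
    "ClusterHierarchy",
    "CompactnessCalibration",
    "MSCConfig",
    "compactness",
    "calibrate_alpha",
    "intra_cluster_connectivity",
    "lambda_permutation_test",
    "evaluate_split",
    "run_msc",
]


def mean_shortest_path(g: nx.Graph) -> float:
    """Mean unweighted shortest-path length over unordered node pairs."""
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("mean shortest path needs >= 2 nodes")
    nodes = list(g.nodes())
    index = {v: k for k, v in enumerate(nodes)}
    rows, cols = [], []
    for u, v in g.edges():
        rows.append(index[u])
        cols.append(index[v])
    adj = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    dist = shortest_path(adj, method="D", directed=False, unweighted=True)
    if np.isinf(dist).any():
        raise ValueError("graph is disconnected; mean shortest path undefined")
    return float(dist.sum() / (n * (n - 1)))


def compactness(subgraph: nx.Graph, alpha: float) -> float:
    """v(alpha) = mean shortest-path distance / (ln N)^alpha (smaller =
    more compact)."""
    n = subgraph.number_of_nodes()
    if n < 3:
        raise ValueError("compactness requires >= 3 nodes")
    if not nx.is_connected(subgraph):
        raise ValueError("compactness requires a connected subgraph")
    return mean_shortest_path(subgraph) / math.log(n) ** alpha


def component_compactness(subgraph: nx.Graph, alpha: float) -> float:
    """Size-weighted mean of per-component compactness.

    Components with < 3 nodes carry no internal distance structure and are
    excluded from the mean; if none qualifies the value is +inf (a split
    into such fragments is never an improvement).
    """
    vals, weights = [], []
    for comp in nx.connected_components(subgraph):
        if len(comp) >= 3:
            vals.append(compactness(subgraph.subgraph(comp), alpha))
            weights.append(len(comp))
    if not vals:
        return math.inf
    return float(np.average(vals, weights=weights))


@dataclass
class CompactnessCalibration:
    alpha_samples: list[float]
    alpha: float
    n_samples: int = 100
    n_layers: int = 3


def calibrate_alpha(
    g: nx.Graph,
    n_samples: int = 100,
    n_layers: int = 3,
    seed: int = 0,
) -> CompactnessCalibration:
    """Estimate the compactness scaling exponent from sampled neighborhoods.

    For each of ``n_samples`` random root nodes, take the subgraph induced
    by nodes within ``n_layers`` hops and compute the reference exponent
    alpha_0 = ln(mean shortest path) / ln(ln N_c); alpha is the median over
    samples with N_c >= 4 (alpha_0 = 0 when the neighborhood is complete,
    i.e. mean shortest path 1).  Falls back to alpha = 1 with < 10 valid
    samples; a value >= 2 is unusual for planar-union networks and is
    logged as a warning.
    """
    if g.number_of_nodes() < 10:
        raise ValueError("alpha calibration needs >= 10 nodes")
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes())
    roots = rng.choice(
        len(nodes), size=n_samples, replace=len(nodes) < n_samples
    )
    samples: list[float] = []
    for r in roots:
        ball = nx.single_source_shortest_path_length(g, nodes[r], cutoff=n_layers)
        if len(ball) < 4:
            continue
        sub = g.subgraph(ball.keys())
        spd = mean_shortest_path(sub)
        if spd <= 1.0:
            samples.append(0.0)
        else:
            samples.append(math.log(spd) / math.log(math.log(len(ball))))
    if len(samples) < 10:
        logger.warning(
            "alpha calibration: only %d valid samples, falling back to alpha=1",
            len(samples),
        )
        return CompactnessCalibration(samples, 1.0, n_samples, n_layers)
    alpha = float(np.median(samples))
    if alpha >= 2:
        logger.warning("calibrated alpha=%.3f >= 2; unusually sparse network", alpha)
    return CompactnessCalibration(samples, alpha, n_samples, n_layers)


def intra_cluster_connectivity(parent_graph: nx.Graph, child_cells: set) -> float:
    """lambda_c: internal edges of the child over edges touching the child."""
    if not child_cells:
        raise ValueError("child cluster is empty")
    missing = child_cells - set(parent_graph.nodes())
    if missing:
        raise ValueError(f"child cells not in parent graph: {sorted(missing)[:5]}")
    internal = incident = 0
    for u, v in parent_graph.edges():
        u_in, v_in = u in child_cells, v in child_cells
        if u_in and v_in:
            internal += 1
            incident += 1
        elif u_in or v_in:
            incident += 1
    if incident == 0:
        return 0.0
    return internal / incident


def _lambda_per_child(
    edge_u_lab: np.ndarray, edge_v_lab: np.ndarray, n_children: int
) -> np.ndarray:
    lam = np.zeros(n_children)
    for c in range(n_children):
        u_in = edge_u_lab == c
        v_in = edge_v_lab == c
        incident = np.count_nonzero(u_in | v_in)
        if incident:
            lam[c] = np.count_nonzero(u_in & v_in) / incident
    return lam


def lambda_permutation_test(
    parent_graph: nx.Graph,
    children: Sequence[set],
    n_perm: int = 100,
    frac: float = 0.10,
    seed: int = 0,
) -> np.ndarray:
    """Permutation p-values for each child's intra-cluster connectivity.

    Each permutation selects a uniform ``frac`` of the parent's cells and
    moves every selected cell to a uniformly chosen *different* child
    (permuting cells across child clusters); the p-value is
    (1 + #{lambda_perm >= lambda_obs}) / (1 + n_perm) per child.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if len(children) < 2:
        raise ValueError("permutation test needs >= 2 children (no split)")
    nodes = sorted(set().union(*children))
    index = {v: k for k, v in enumerate(nodes)}
    labels = np.full(len(nodes), -1, dtype=int)
    for c, members in enumerate(children):
        for v in members:
            if labels[index[v]] != -1:
                raise ValueError("children must be disjoint")
            labels[index[v]] = c

    edges = [
        (index[u], index[v])
        for u, v in parent_graph.edges()
        if u in index and v in index
    ]
    eu = np.array([e[0] for e in edges], dtype=int)
    ev = np.array([e[1] for e in edges], dtype=int)

    n_children = len(children)
    lam_obs = _lambda_per_child(labels[eu], labels[ev], n_children)
    n_move = max(1, math.ceil(frac * len(nodes)))
    n_move = min(n_move, len(nodes))
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_children)
    for _ in range(n_perm):
        perm_labels = labels.copy()
        sel = rng.choice(len(nodes), size=n_move, replace=False)
        # move each selected cell to a uniformly chosen other child
        shift = rng.integers(1, n_children, size=n_move)
        perm_labels[sel] = (perm_labels[sel] + shift) % n_children
        lam_perm = _lambda_per_child(perm_labels[eu], perm_labels[ev], n_children)
        exceed += lam_perm >= lam_obs
    return (1.0 + exceed) / (1.0 + n_perm)


@dataclass
class ClusterNode:
    """One cluster in the hierarchy (id style M1, M2, ...)."""

    id: str
    cells: set
    parent: Optional[str]
    children: list[str] = field(default_factory=list)
    gamma_f: Optional[float] = None
    v_alpha: Optional[float] = None
    lam: Optional[float] = None
    lambda_p: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def size(self) -> int:
        return len(self.cells)


@dataclass
class ClusterHierarchy:
    nodes: dict[str, ClusterNode]
    roots: list[str]
    unassigned: set
    cell_ids: list[str]
    alpha_by_root: dict[str, float] = field(default_factory=dict)

    def cluster_sets(self, use_ids: bool = True) -> dict[str, set]:
        """All hierarchy nodes (internal + leaf) as overlapping clusters."""
        if use_ids:
            return {
                nid: {self.cell_ids[c] for c in node.cells}
                for nid, node in self.nodes.items()
            }
        return {nid: set(node.cells) for nid, node in self.nodes.items()}

    def membership(self) -> list[tuple[str, str]]:
        """Long-format (cell_id, node_id) rows, internal nodes included."""
        rows = []
        for nid, node in sorted(self.nodes.items(), key=lambda kv: kv[1].size, reverse=True):
            for c in sorted(node.cells):
                rows.append((self.cell_ids[c], nid))
        return rows

    def to_dict(self) -> dict:
        return {
            "roots": self.roots,
            "unassigned": sorted(self.cell_ids[c] for c in self.unassigned),
            "alpha_by_root": self.alpha_by_root,
            "nodes": {
                nid: {
                    "parent": node.parent,
                    "children": node.children,
                    "size": node.size,
                    "gamma_f": node.gamma_f,
                    "v_alpha": node.v_alpha,
                    "lambda": node.lam,
                    "lambda_p": node.lambda_p,
                }
                for nid, node in self.nodes.items()
            },
        }

    def to_newick(self) -> str:
        def render(nid: str) -> str:
            node = self.nodes[nid]
            label = f"{nid}_{node.size}"
            if node.is_leaf:
                return label
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){label}"

        return "(" + ",".join(render(r) for r in self.roots) + ")root;"


@dataclass
class MSCConfig:
    min_cluster_size: int = 10
    min_split_size: int = 20
    gamma_grid: Optional[Sequence[float]] = None
    n_perm: int = 100
    perm_frac: float = 0.10
    p_threshold: float = 0.05
    alpha: Optional[float] = None  # None = calibrate per top-level component
    seed: int = 0


def evaluate_split(
    parent_subgraph: nx.Graph,
    candidate_children: Sequence[set],
    alpha: float,
    config: MSCConfig,
    perm_seed: int,
) -> list[tuple[set, float, float]]:
    """Gate candidate children on size, compactness and connectivity.

    Returns (cells, lambda, p) for each accepted child: size >=
    min_cluster_size, component-wise compactness strictly below the
    parent's, and permutation p-value below the threshold.
    """
    if len(candidate_children) < 2:
        raise ValueError("evaluate_split needs >= 2 candidate children")
    # a disconnected parent has no finite mean shortest path as a single
    # cluster: any coherent split improves on it
    if nx.is_connected(parent_subgraph):
        v_parent = component_compactness(parent_subgraph, alpha)
    else:
        v_parent = math.inf
    pvals = lambda_permutation_test(
        parent_subgraph,
        candidate_children,
        n_perm=config.n_perm,
        frac=config.perm_frac,
        seed=perm_seed,
    )
    accepted = []
    for c, cells in enumerate(candidate_children):
        if len(cells) < config.min_cluster_size:
            continue
        v_child = component_compactness(parent_subgraph.subgraph(cells), alpha)
        if not v_child < v_parent:
            continue
        if not pvals[c] < config.p_threshold:
            continue
        lam = intra_cluster_connectivity(parent_subgraph, cells)
        accepted.append((cells, lam, float(pvals[c])))
    return accepted


def run_msc(g_o: nx.Graph, config: Optional[MSCConfig] = None) -> ClusterHierarchy:
    """Full top-down pass over the screened network G_o.

    Connected components at or above ``min_cluster_size`` become root
    clusters; every node with >= ``min_split_size`` cells is split by
    AdaptSplit and its children gated by :func:`evaluate_split`; recursion
    continues on accepted children.  Cells of components below the size
    floor are reported as unassigned.
    """
    if g_o.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    if g_o.graph.get("stage") not in (None, "final"):
        logger.warning("run_msc on a graph at stage %r", g_o.graph.get("stage"))
    config = config or MSCConfig()
    cell_ids = g_o.graph.get(
        "cell_ids", [str(v) for v in range(g_o.number_of_nodes())]
    )

    nodes: dict[str, ClusterNode] = {}
    roots: list[str] = []
    unassigned: set = set()
    alpha_by_root: dict[str, float] = {}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"M{counter}"

    components = sorted(nx.connected_components(g_o), key=lambda c: (-len(c), min(c)))
    leiden_seed = stage_seed(config.seed, "leiden")
    split_counter = 0

    # breadth-first over the hierarchy so ids follow the split order
    queue: list[str] = []
    for comp in components:
        if len(comp) < config.min_cluster_size:
            unassigned |= comp
            continue
        nid = next_id()
        sub = g_o.subgraph(comp)
        nodes[nid] = ClusterNode(
            id=nid,
            cells=set(comp),
            parent=None,
            v_alpha=None,
        )
        roots.append(nid)
        if config.alpha is not None:
            alpha = config.alpha
        else:
            try:
                alpha = calibrate_alpha(
                    sub, seed=stage_seed(config.seed, "alpha", len(roots))
                ).alpha
            except ValueError:
                alpha = 1.0
        alpha_by_root[nid] = alpha
        nodes[nid].v_alpha = component_compactness(sub, alpha)
        queue.append(nid)

    root_of: dict[str, str] = {r: r for r in roots}
    while queue:
        nid = queue.pop(0)
        node = nodes[nid]
        if node.size < config.min_split_size:
            continue
        sub = g_o.subgraph(node.cells)
        alpha = alpha_by_root[root_of[nid]]
        result = adapt_split(sub, grid=config.gamma_grid, seed=leiden_seed)
        if result.no_split:
            continue
        split_counter += 1
        perm_seed = stage_seed(config.seed, "perm", split_counter)
        accepted = evaluate_split(sub, result.partition, alpha, config, perm_seed)
        if not accepted:
            continue
        node.gamma_f = result.gamma_f
        for cells, lam, p in sorted(accepted, key=lambda t: (-len(t[0]), min(t[0]))):
            cid = next_id()
            child_sub = sub.subgraph(cells)
            nodes[cid] = ClusterNode(
                id=cid,
                cells=set(cells),
                parent=nid,
                v_alpha=component_compactness(child_sub, alpha),
                lam=lam,
                lambda_p=p,
            )
            node.children.append(cid)
            root_of[cid] = root_of[nid]
            queue.append(cid)

    return ClusterHierarchy(
        nodes=nodes,
        roots=roots,
        unassigned=unassigned,
        cell_ids=list(cell_ids),
        alpha_by_root=alpha_by_root,
    )
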