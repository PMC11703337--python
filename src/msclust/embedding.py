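"""Locally embedded network (LEN) construction.

For every cell, a planar maximally filtered graph (PMFG) is built on the
cell plus its k most similar cells for growing k; the cells adjacent to the
focal cell stabilize ("saturate") as k grows, and those stabilized embedded
neighbors define the cell's local star.  The union of all per-cell stars is
the raw LEN, a sparse weighted cell graph (planarity bounds each local
graph at 3(N-2) edges by Euler's relation, so the union stays sparse
without any user-chosen k).

Graphs are ``networkx.Graph`` objects whose nodes are integer cell indices;
``G.graph`` carries ``cell_ids``, the similarity ``mode`` and the pipeline
``stage``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from ._planarity import is_planar_edges
from .similarity import SimilarityMatrix

__all__ = [
    "NeighborResult",
    "pmfg",
    "local_embedding",
    "assemble_len",
    "build_len",
]


@dataclass
class NeighborResult:
    """Embedded neighbors of one cell and the k at which they stabilized."""

    cell: int
    neighbors: tuple[int, ...]
    k_saturation: int


def _candidate_edges(sim: np.ndarray, nodes: Sequence[int]):
    """Candidate edges sorted by (similarity desc, smaller idx, larger idx)."""
    nodes = list(nodes)
    cand = []
    for a in range(len(nodes)):
        u = nodes[a]
        for b in range(a + 1, len(nodes)):
            v = nodes[b]
            i, j = (u, v) if u < v else (v, u)
            cand.append((-sim[i, j], i, j))
    cand.sort()
    return cand


def _pmfg_edges(sim: np.ndarray, nodes: list) -> list:
    """Greedy PMFG edge selection; returns accepted (i, j, weight) tuples."""
    n = len(nodes)
    index = {v: k for k, v in enumerate(nodes)}
    cap = 1 if n == 2 else 3 * (n - 2)
    eu = np.empty(cap + 1, dtype=np.int64)
    ev = np.empty(cap + 1, dtype=np.int64)
    accepted: list = []
    m = 0
    for negw, i, j in _candidate_edges(sim, nodes):
        eu[m] = index[i]
        ev[m] = index[j]
        if is_planar_edges(n, eu[: m + 1], ev[: m + 1]):
            accepted.append((i, j, -negw))
            m += 1
            if m >= cap:
                break
    return accepted


def pmfg(sim: np.ndarray, nodes: Sequence[int]) -> nx.Graph:
    """Planar maximally filtered graph on a node subset.

    Greedy: iterate candidate edges in decreasing similarity and insert an
    edge iff the graph stays planar (exact test), stopping at the Euler
    bound of 3(N-2) edges.  For N <= 4 this yields the complete graph; N = 2
    yields the single edge.
    """
    nodes = list(nodes)
    if len(nodes) < 2:
        raise ValueError("pmfg needs at least 2 nodes")
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_weighted_edges_from(_pmfg_edges(sim, nodes))
    return g


def _neighbor_order(sim: np.ndarray, cell: int) -> np.ndarray:
    """All other cells ordered by (similarity desc, index asc)."""
    n = sim.shape[0]
    others = np.array([j for j in range(n) if j != cell])
    order = np.lexsort((others, -sim[cell, others]))
    return others[order]


def default_k_max(n_cells: int) -> int:
    """Upper bound on the neighborhood size scan, ~3 ln(N) in practice."""
    return max(10, math.ceil(3.0 * math.log(n_cells)))


def local_embedding(
    cell: int,
    sim: np.ndarray,
    stall: int = 3,
    k_max: Optional[int] = None,
) -> NeighborResult:
    """Grow k from 3 until the focal cell's PMFG adjacency plateaus.

    The plateau is declared after ``stall`` consecutive k increments with an
    unchanged adjacency set, or at ``k_max``.  Cells with fewer than 3 other
    cells get all of them as neighbors.
    """
    n = sim.shape[0]
    if n - 1 <= 3:
        others = tuple(int(j) for j in _neighbor_order(sim, cell))
        return NeighborResult(cell=cell, neighbors=others, k_saturation=n - 1)
    if k_max is None:
        k_max = default_k_max(n)
    k_max = min(k_max, n - 1)
    order = _neighbor_order(sim, cell)

    prev: Optional[frozenset] = None
    k_prime = 3
    streak = 0
    for k in range(3, k_max + 1):
        local_nodes = [cell] + [int(j) for j in order[:k]]
        accepted = _pmfg_edges(sim, local_nodes)
        adj = frozenset(
            (b if a == cell else a) for a, b, _ in accepted if cell in (a, b)
        )
        if adj == prev:
            streak += 1
            if streak >= stall:
                break
        else:
            prev = adj
            streak = 0
            k_prime = k
    assert prev is not None and prev
    return NeighborResult(
        cell=cell,
        neighbors=tuple(sorted(prev)),
        k_saturation=k_prime,
    )


def assemble_len(
    results: Sequence[NeighborResult],
    sim: SimilarityMatrix,
) -> nx.Graph:
    """Union of the per-cell stars: edge (i,j) iff j in NN_i or i in NN_j."""
    g = nx.Graph(cell_ids=list(sim.cell_ids), mode=sim.mode, stage="raw_union")
    g.add_nodes_from(range(sim.n_cells))
    for res in results:
        for j in res.neighbors:
            g.add_edge(res.cell, j, weight=float(sim.values[res.cell, j]))
    return g


def build_len(
    sim: SimilarityMatrix,
    stall: int = 3,
    k_max: Optional[int] = None,
) -> nx.Graph:
    """Run the local embedding for every cell and union the results."""
    if sim.n_cells < 2:
        raise ValueError("need at least 2 cells to build a network")
    results = [
        local_embedding(i, sim.values, stall=stall, k_max=k_max)
        for i in range(sim.n_cells)
    ]
    return assemble_len(results, sim)
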