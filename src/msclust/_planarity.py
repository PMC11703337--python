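"""Fast boolean planarity test (left-right criterion).

The PMFG construction performs one exact planarity test per candidate edge
insertion, which dominates the cost of building a locally embedded
network.  This module implements the left-right planarity test of Brandes
(the same criterion networkx uses) on flat integer arrays, compiled with
numba when available, and — unlike a general-purpose implementation —
stops after the testing phase: no combinatorial embedding is constructed,
because only the yes/no answer is needed.

Correctness is cross-validated against ``networkx.check_planarity`` in the
test suite on thousands of random graphs around the planarity threshold.
"""

from __future__ import annotations

import numpy as np

__all__ = ["is_planar_edges"]

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=False)
def _lr_planar(n: int, eu: np.ndarray, ev: np.ndarray) -> bool:
    m = eu.shape[0]
    if n > 2 and m > 3 * n - 6:
        return False
    if m <= 8:
        # any graph with at most 8 edges is planar (K5 has 10, K3,3 has 9)
        return True

    # CSR adjacency over both edge directions
    deg = np.zeros(n + 1, np.int64)
    for k in range(m):
        deg[eu[k] + 1] += 1
        deg[ev[k] + 1] += 1
    for v in range(n):
        deg[v + 1] += deg[v]
    adj_start = deg
    fill = adj_start[:n].copy()
    adj_nbr = np.empty(2 * m, np.int64)
    adj_eid = np.empty(2 * m, np.int64)
    for k in range(m):
        u, v = eu[k], ev[k]
        adj_nbr[fill[u]] = v
        adj_eid[fill[u]] = k
        fill[u] += 1
        adj_nbr[fill[v]] = u
        adj_eid[fill[v]] = k
        fill[v] += 1

    NONE = np.int64(-1)
    height = np.full(n, NONE, np.int64)
    parent_edge = np.full(n, NONE, np.int64)
    oriented = np.zeros(m, np.uint8)
    esrc = np.full(m, NONE, np.int64)
    edst = np.full(m, NONE, np.int64)
    lowpt = np.zeros(m, np.int64)
    lowpt2 = np.zeros(m, np.int64)
    nesting = np.zeros(m, np.int64)
    ind = np.zeros(n, np.int64)
    skip_init = np.zeros(m, np.uint8)
    stack = np.empty(2 * n + 2, np.int64)
    roots = np.empty(n, np.int64)
    n_roots = 0

    # phase 1: DFS orientation, lowpoints, nesting depth
    for r in range(n):
        if height[r] != NONE:
            continue
        height[r] = 0
        roots[n_roots] = r
        n_roots += 1
        sp = 0
        stack[0] = r
        while sp >= 0:
            v = stack[sp]
            sp -= 1
            e = parent_edge[v]
            descend = False
            while ind[v] < adj_start[v + 1] - adj_start[v]:
                ptr = adj_start[v] + ind[v]
                w = adj_nbr[ptr]
                eid = adj_eid[ptr]
                if skip_init[eid] == 0:
                    if oriented[eid] == 1:
                        ind[v] += 1
                        continue
                    oriented[eid] = 1
                    esrc[eid] = v
                    edst[eid] = w
                    lowpt[eid] = height[v]
                    lowpt2[eid] = height[v]
                    if height[w] == NONE:  # tree edge
                        parent_edge[w] = eid
                        height[w] = height[v] + 1
                        sp += 1
                        stack[sp] = v
                        sp += 1
                        stack[sp] = w
                        skip_init[eid] = 1
                        descend = True
                        break
                    else:  # back edge
                        lowpt[eid] = height[w]
                nesting[eid] = 2 * lowpt[eid]
                if lowpt2[eid] < height[v]:  # chordal
                    nesting[eid] += 1
                if e != NONE:
                    if lowpt[eid] < lowpt[e]:
                        lowpt2[e] = min(lowpt[e], lowpt2[eid])
                        lowpt[e] = lowpt[eid]
                    elif lowpt[eid] > lowpt[e]:
                        lowpt2[e] = min(lowpt2[e], lowpt[eid])
                    else:
                        lowpt2[e] = min(lowpt2[e], lowpt2[eid])
                ind[v] += 1
            if descend:
                continue

    # ordered out-adjacency, sorted by nesting depth (stable insertion sort)
    out_start = np.zeros(n + 1, np.int64)
    for d in range(m):
        out_start[esrc[d] + 1] += 1
    for v in range(n):
        out_start[v + 1] += out_start[v]
    ofill = out_start[:n].copy()
    out_eid = np.empty(m, np.int64)
    for d in range(m):
        s = esrc[d]
        out_eid[ofill[s]] = d
        ofill[s] += 1
    for v in range(n):
        lo = out_start[v]
        hi = out_start[v + 1]
        for a in range(lo + 1, hi):
            key = out_eid[a]
            kn = nesting[key]
            b = a - 1
            while b >= lo and nesting[out_eid[b]] > kn:
                out_eid[b + 1] = out_eid[b]
                b -= 1
            out_eid[b + 1] = key

    # phase 2: testing with a stack of conflict pairs.
    # pair pool: left/right intervals of (low, high) directed-edge ids
    cap_pairs = 2 * m + 8
    l_lo = np.full(cap_pairs, NONE, np.int64)
    l_hi = np.full(cap_pairs, NONE, np.int64)
    r_lo = np.full(cap_pairs, NONE, np.int64)
    r_hi = np.full(cap_pairs, NONE, np.int64)
    n_pairs = 0
    pair_stack = np.empty(cap_pairs + 4, np.int64)
    sp_s = -1
    stack_bottom = np.full(m, NONE, np.int64)
    lowpt_edge = np.full(m, NONE, np.int64)
    ref = np.full(m, NONE, np.int64)
    ind2 = np.zeros(n, np.int64)
    skip_init2 = np.zeros(m, np.uint8)

    for ri in range(n_roots):
        sp = 0
        stack[0] = roots[ri]
        while sp >= 0:
            v = stack[sp]
            sp -= 1
            e = parent_edge[v]
            skip_final = False
            while ind2[v] < out_start[v + 1] - out_start[v]:
                ptr = out_start[v] + ind2[v]
                ei = out_eid[ptr]
                w = edst[ei]
                if skip_init2[ei] == 0:
                    stack_bottom[ei] = pair_stack[sp_s] if sp_s >= 0 else NONE
                    if ei == parent_edge[w]:  # tree edge
                        sp += 1
                        stack[sp] = v
                        sp += 1
                        stack[sp] = w
                        skip_init2[ei] = 1
                        skip_final = True
                        break
                    else:  # back edge
                        lowpt_edge[ei] = ei
                        p = n_pairs
                        n_pairs += 1
                        l_lo[p] = NONE
                        l_hi[p] = NONE
                        r_lo[p] = ei
                        r_hi[p] = ei
                        sp_s += 1
                        pair_stack[sp_s] = p
                # integrate new return edges
                if lowpt[ei] < height[v]:
                    if ptr == out_start[v]:  # first ordered edge of v
                        lowpt_edge[e] = lowpt_edge[ei]
                    else:
                        # --- add_constraints(ei, e) ---
                        p = n_pairs
                        n_pairs += 1
                        l_lo[p] = NONE
                        l_hi[p] = NONE
                        r_lo[p] = NONE
                        r_hi[p] = NONE
                        # merge return edges of ei into p.right
                        while True:
                            q = pair_stack[sp_s]
                            sp_s -= 1
                            if not (l_lo[q] == NONE and l_hi[q] == NONE):
                                tl = l_lo[q]
                                th = l_hi[q]
                                l_lo[q] = r_lo[q]
                                l_hi[q] = r_hi[q]
                                r_lo[q] = tl
                                r_hi[q] = th
                            if not (l_lo[q] == NONE and l_hi[q] == NONE):
                                return False  # not planar
                            if lowpt[r_lo[q]] > lowpt[e]:
                                if r_lo[p] == NONE and r_hi[p] == NONE:
                                    r_hi[p] = r_hi[q]
                                elif r_lo[p] != NONE:
                                    ref[r_lo[p]] = r_hi[q]
                                r_lo[p] = r_lo[q]
                            else:  # align
                                ref[r_lo[q]] = lowpt_edge[e]
                            top = pair_stack[sp_s] if sp_s >= 0 else NONE
                            if top == stack_bottom[ei]:
                                break
                        # merge conflicting return edges into p.left
                        while sp_s >= 0:
                            q = pair_stack[sp_s]
                            confl_l = (
                                not (l_lo[q] == NONE and l_hi[q] == NONE)
                            ) and lowpt[l_hi[q]] > lowpt[ei]
                            confl_r = (
                                not (r_lo[q] == NONE and r_hi[q] == NONE)
                            ) and lowpt[r_hi[q]] > lowpt[ei]
                            if not (confl_l or confl_r):
                                break
                            sp_s -= 1
                            if confl_r:
                                tl = l_lo[q]
                                th = l_hi[q]
                                l_lo[q] = r_lo[q]
                                l_hi[q] = r_hi[q]
                                r_lo[q] = tl
                                r_hi[q] = th
                            if (
                                not (r_lo[q] == NONE and r_hi[q] == NONE)
                            ) and lowpt[r_hi[q]] > lowpt[ei]:
                                return False  # not planar
                            # merge interval below lowpt(ei) into p.right
                            if r_lo[p] != NONE:
                                ref[r_lo[p]] = r_hi[q]
                            if r_lo[q] != NONE:
                                r_lo[p] = r_lo[q]
                            if l_lo[p] == NONE and l_hi[p] == NONE:
                                l_hi[p] = l_hi[q]
                            elif l_lo[p] != NONE:
                                ref[l_lo[p]] = l_hi[q]
                            l_lo[p] = l_lo[q]
                        if not (
                            l_lo[p] == NONE
                            and l_hi[p] == NONE
                            and r_lo[p] == NONE
                            and r_hi[p] == NONE
                        ):
                            sp_s += 1
                            pair_stack[sp_s] = p
                        # --- end add_constraints ---
                ind2[v] += 1
            if not skip_final and e != NONE:
                # --- remove_back_edges(e) ---
                u = esrc[e]
                while sp_s >= 0:
                    q = pair_stack[sp_s]
                    if l_lo[q] == NONE and l_hi[q] == NONE:
                        low_val = lowpt[r_lo[q]]
                    elif r_lo[q] == NONE and r_hi[q] == NONE:
                        low_val = lowpt[l_lo[q]]
                    else:
                        low_val = min(lowpt[l_lo[q]], lowpt[r_lo[q]])
                    if low_val != height[u]:
                        break
                    sp_s -= 1  # drop whole pair
                if sp_s >= 0:
                    q = pair_stack[sp_s]
                    sp_s -= 1
                    while l_hi[q] != NONE and edst[l_hi[q]] == u:
                        l_hi[q] = ref[l_hi[q]]
                    if l_hi[q] == NONE and l_lo[q] != NONE:
                        ref[l_lo[q]] = r_lo[q]
                        l_lo[q] = NONE
                    while r_hi[q] != NONE and edst[r_hi[q]] == u:
                        r_hi[q] = ref[r_hi[q]]
                    if r_hi[q] == NONE and r_lo[q] != NONE:
                        ref[r_lo[q]] = l_lo[q]
                        r_lo[q] = NONE
                    sp_s += 1
                    pair_stack[sp_s] = q
                # (the side/ref bookkeeping for e feeds only the embedding
                # phase, which this boolean test does not run)
                # --- end remove_back_edges ---
    return True


def _is_planar_networkx(n: int, eu: np.ndarray, ev: np.ndarray) -> bool:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(eu.tolist(), ev.tolist()))
    return nx.check_planarity(g, counterexample=False)[0]


def is_planar_edges(n: int, eu, ev) -> bool:
    """Exact planarity of the simple graph on nodes 0..n-1 with the given
    edge arrays."""
    eu = np.asarray(eu, dtype=np.int64)
    ev = np.asarray(ev, dtype=np.int64)
    if _HAVE_NUMBA:
        return bool(_lr_planar(n, eu, ev))
    return _is_planar_networkx(n, eu, ev)  # pragma: no cover
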