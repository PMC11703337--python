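import math

import networkx as nx
import numpy as np
import pytest

from msclust.hierarchy import (
    MSCConfig,
    calibrate_alpha,
    compactness,
    component_compactness,
    evaluate_split,
    intra_cluster_connectivity,
    lambda_permutation_test,
    mean_shortest_path,
    run_msc,
)


def _bfs_mean_spd(g):
    """Brute-force BFS oracle for the mean shortest-path distance."""
    nodes = list(g.nodes())
    total = count = 0
    for i, s in enumerate(nodes):
        dist = {s: 0}
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for w in g.neighbors(u):
                    if w not in dist:
                        dist[w] = d
                        nxt.append(w)
            frontier = nxt
        for t in nodes[i + 1 :]:
            total += dist[t]
            count += 1
    return total / count


class TestCompactness:
    def test_complete_graph_closed_form(self):
        for n in (4, 7, 10):
            g = nx.complete_graph(n)
            assert compactness(g, 1.3) == pytest.approx(1.0 / math.log(n) ** 1.3)

    def test_path_of_three(self):
        g = nx.path_graph(3)
        assert compactness(g, 1.0) == pytest.approx((4 / 3) / math.log(3))

    def test_alpha_zero_is_mean_spd(self):
        g = nx.cycle_graph(7)
        assert compactness(g, 0.0) == pytest.approx(mean_shortest_path(g))

    def test_against_bfs_oracle(self):
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 15:
            n = int(rng.integers(5, 51))
            g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(2**31)))
            if not nx.is_connected(g):
                continue
            checked += 1
            assert mean_shortest_path(g) == pytest.approx(_bfs_mean_spd(g))

    def test_disconnected_rejected(self):
        g = nx.Graph([(0, 1), (2, 3), (1, 2)])
        g.remove_edge(1, 2)
        g.add_edge(0, 2)
        g.add_node(9)
        with pytest.raises(ValueError, match="connected"):
            compactness(g, 1.0)

    def test_component_compactness_weighted_mean(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.path_graph(3))
        v4 = compactness(nx.complete_graph(4), 1.0)
        v3 = compactness(nx.path_graph(3), 1.0)
        assert component_compactness(g, 1.0) == pytest.approx((4 * v4 + 3 * v3) / 7)


class TestCalibrateAlpha:
    def test_complete_graph_alpha_zero(self):
        cal = calibrate_alpha(nx.complete_graph(20), seed=0)
        assert cal.alpha == 0.0

    def test_deterministic(self):
        g = nx.random_geometric_graph(60, 0.25, seed=4)
        a = calibrate_alpha(g, seed=9)
        b = calibrate_alpha(g, seed=9)
        assert a.alpha == b.alpha

    def test_sparse_network_alpha_below_two(self):
        g = nx.random_geometric_graph(200, 0.12, seed=1)
        cal = calibrate_alpha(g, seed=0)
        assert 0 <= cal.alpha < 2


class TestLambda:
    def test_whole_parent_is_one(self):
        g = nx.complete_graph(6)
        assert intra_cluster_connectivity(g, set(range(6))) == 1.0

    def test_single_node_is_zero(self):
        g = nx.star_graph(4)
        assert intra_cluster_connectivity(g, {1}) == 0.0

    def test_worked_ratio(self):
        # child {0,1,2,3}: path 0-1-2-3 plus chord 0-2 = 4 internal edges,
        # one boundary edge 3-4
        g = nx.Graph([(0, 1), (1, 2), (2, 3), (0, 2), (3, 4), (4, 5)])
        assert intra_cluster_connectivity(g, {0, 1, 2, 3}) == pytest.approx(0.8)

    def test_permutation_p_matches_exhaustive_enumeration(self, two_cliques):
        """Monte-carlo p-values against the exhaustively enumerated null on
        the 12-node two-clique instance (2 cells moved per permutation)."""
        children = [set(range(6)), set(range(6, 12))]

        def brute_lambda(labels, child):
            internal = incident = 0
            for u, v in two_cliques.edges():
                u_in, v_in = labels[u] == child, labels[v] == child
                internal += u_in and v_in
                incident += u_in or v_in
            return internal / incident if incident else 0.0

        base = [0] * 6 + [1] * 6
        # with two children each selected cell deterministically moves to
        # the other one; enumerate all C(12,2) selections
        worst = {0: 0, 1: 0}
        n_sel = 0
        for x in range(12):
            for y in range(x + 1, 12):
                labels = list(base)
                labels[x] = 1 - labels[x]
                labels[y] = 1 - labels[y]
                n_sel += 1
                for child in (0, 1):
                    worst[child] += brute_lambda(labels, child) >= 1.0
        assert n_sel == math.comb(12, 2)
        assert worst == {0: 0, 1: 0}  # every move breaks both cliques
        # hence the exact p-value is the minimum attainable, 1/(1+n_perm)
        pvals = lambda_permutation_test(
            two_cliques, children, n_perm=100, frac=0.10, seed=5
        )
        assert np.all(pvals == pytest.approx(1 / 101))

    def test_random_children_large_p(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(60, 0.2, seed=11)
        labels = rng.integers(0, 2, size=60)
        children = [set(np.flatnonzero(labels == c)) for c in (0, 1)]
        pvals = lambda_permutation_test(g, children, n_perm=200, frac=0.1, seed=2)
        assert np.all(pvals > 0.05)

    def test_separated_children_significant(self):
        g = nx.disjoint_union(nx.complete_graph(30), nx.complete_graph(30))
        children = [set(range(30)), set(range(30, 60))]
        pvals = lambda_permutation_test(g, children, n_perm=100, frac=0.1, seed=1)
        assert np.all(pvals == pytest.approx(1 / 101))

    def test_preconditions(self, two_cliques):
        with pytest.raises(ValueError, match="n_perm"):
            lambda_permutation_test(two_cliques, [{0}, {1}], n_perm=0)
        with pytest.raises(ValueError, match="no split"):
            lambda_permutation_test(two_cliques, [set(range(12))])


class TestEvaluateSplit:
    def test_separated_cliques_accepted(self):
        g = nx.disjoint_union(nx.complete_graph(30), nx.complete_graph(30))
        children = [set(range(30)), set(range(30, 60))]
        accepted = evaluate_split(g, children, alpha=1.0, config=MSCConfig(), perm_seed=0)
        assert len(accepted) == 2
        for cells, lam, p in accepted:
            assert lam == 1.0
            assert p < 0.05

    def test_random_bisection_of_clique_rejected(self):
        g = nx.complete_graph(40)
        children = [set(range(20)), set(range(20, 40))]
        accepted = evaluate_split(g, children, alpha=1.0, config=MSCConfig(), perm_seed=0)
        assert accepted == []

    def test_undersized_candidate_rejected_regardless(self):
        g = nx.disjoint_union(nx.complete_graph(30), nx.complete_graph(5))
        children = [set(range(30)), set(range(30, 35))]
        accepted = evaluate_split(g, children, alpha=1.0, config=MSCConfig(), perm_seed=0)
        assert all(len(cells) >= 10 for cells, _, _ in accepted)
        assert not any(cells == set(range(30, 35)) for cells, _, _ in accepted)


class TestRunMsc:
    def test_disconnected_cliques_become_roots_and_terminate(self):
        g = nx.disjoint_union(nx.complete_graph(15), nx.complete_graph(15))
        g.graph["stage"] = "final"
        h = run_msc(g, MSCConfig(seed=0))
        assert len(h.roots) == 2
        assert sorted(h.nodes[r].size for r in h.roots) == [15, 15]
        # no improving split inside a clique
        assert all(h.nodes[r].is_leaf for r in h.roots)

    def test_nesting_and_disjoint_siblings(self, three_block_sim):
        from msclust import build_len

        g = build_len(three_block_sim)
        h = run_msc(g, MSCConfig(seed=0))
        for node in h.nodes.values():
            if node.parent is not None:
                assert node.cells <= h.nodes[node.parent].cells
            kids = [h.nodes[c].cells for c in node.children]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    assert not (kids[a] & kids[b])
                assert kids[a] <= node.cells

    def test_three_blocks_recovered(self, three_block_dataset, three_block_sim):
        from msclust import build_len
        from msclust.metrics import jaccard_index

        g = build_len(three_block_sim)
        h = run_msc(g, MSCConfig(seed=0))
        clusters = h.cluster_sets()
        for truth in three_block_dataset.inner_clusters().values():
            assert max(jaccard_index(c, truth) for c in clusters.values()) >= 0.9

    def test_determinism(self, three_block_sim):
        from msclust import build_len

        g = build_len(three_block_sim)
        h1 = run_msc(g, MSCConfig(seed=3))
        h2 = run_msc(g, MSCConfig(seed=3))
        assert h1.to_dict() == h2.to_dict()

    def test_membership_covers_every_path_node(self, three_block_sim):
        from msclust import build_len

        g = build_len(three_block_sim)
        h = run_msc(g, MSCConfig(seed=0))
        rows = set(h.membership())
        for nid, node in h.nodes.items():
            for c in node.cells:
                assert (h.cell_ids[c], nid) in rows

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            run_msc(nx.Graph())

    def test_newick_export_parses(self, three_block_sim):
        from io import StringIO

        from Bio import Phylo

        from msclust import build_len

        g = build_len(three_block_sim)
        h = run_msc(g, MSCConfig(seed=0))
        tree = Phylo.read(StringIO(h.to_newick()), "newick")
        names = {cl.name for cl in tree.find_clades() if cl.name}
        assert any(name.startswith("M1_") for name in names)
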