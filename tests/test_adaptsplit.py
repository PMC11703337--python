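import networkx as nx
import numpy as np
import pytest

from msclust.adaptsplit import (
    GammaScan,
    _step_split_indices,
    adapt_split,
    default_gamma_grid,
    detect_first_breakpoint,
    intra_cluster_links,
    scan_resolutions,
)


def _scan(gammas, kin):
    gammas = np.asarray(gammas, dtype=float)
    kin = np.asarray(kin, dtype=float)
    return GammaScan(
        gammas=gammas,
        clusterings=[[] for _ in gammas],
        kin=kin,
        n_clusters=np.zeros(len(gammas), dtype=int),
    )


def _two_cliques_bridge(k=6):
    g = nx.disjoint_union(nx.complete_graph(k), nx.complete_graph(k))
    g.add_edge(0, k)
    return g


class TestIntraClusterLinks:
    def test_single_cluster_counts_all_edges(self):
        g = nx.complete_graph(5)
        assert intra_cluster_links(g, [set(range(5))]) == 10

    def test_singletons_count_zero(self):
        g = nx.complete_graph(5)
        assert intra_cluster_links(g, [{i} for i in range(5)]) == 0

    def test_four_cycle_split_into_pairs(self):
        g = nx.cycle_graph(4)
        assert intra_cluster_links(g, [{0, 1}, {2, 3}]) == 2

    def test_missing_node_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError, match="cover"):
            intra_cluster_links(g, [{0, 1}])

    def test_monotone_under_refinement(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            g = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(2**31)))
            labels = rng.integers(0, 3, size=15)
            coarse = [set(np.flatnonzero(labels == c)) for c in range(3)]
            coarse = [c for c in coarse if c]
            # refine by splitting one cluster at random
            fine = []
            for c in coarse:
                c = sorted(c)
                cut = rng.integers(0, len(c) + 1)
                if 0 < cut < len(c):
                    fine.extend([set(c[:cut]), set(c[cut:])])
                else:
                    fine.append(set(c))
            assert intra_cluster_links(g, fine) <= intra_cluster_links(g, coarse)


class TestBreakpointDetection:
    def test_two_step_sequence(self):
        scan = _scan([0.1, 0.2, 0.3, 0.4, 0.5, 0.6], [10, 10, 10, 6, 6, 2])
        gamma_prime, regime = detect_first_breakpoint(scan)
        assert 0.3 < gamma_prime < 0.4
        assert np.array_equal(scan.gammas[regime], [0.1, 0.2, 0.3])

    def test_constant_kin_no_breakpoint(self):
        scan = _scan([0.1, 0.2, 0.3, 0.4, 0.5], [7, 7, 7, 7, 7])
        gamma_prime, regime = detect_first_breakpoint(scan)
        assert gamma_prime == 0.5
        assert len(regime) == 5

    def test_single_step(self):
        scan = _scan([0.1, 0.2, 0.3, 0.4, 0.5], [10, 10, 2, 2, 2])
        gamma_prime, regime = detect_first_breakpoint(scan)
        assert 0.2 < gamma_prime < 0.3
        assert len(regime) == 2

    def test_affine_invariance(self):
        kin = np.array([30, 30, 30, 12, 12, 12, 4, 4], dtype=float)
        gammas = np.round(np.arange(1, 9) * 0.1, 10)
        base = _step_split_indices(kin)
        assert base == _step_split_indices(5.0 * kin - 17.0)
        assert base == _step_split_indices(kin / 1000.0)

    def test_top_split_matches_exhaustive_sse_search(self):
        """The first split equals the exhaustive single-split SSE minimizer
        (independent cumulative-sum oracle) on random step sequences."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(8, 41))
            n_steps = int(rng.integers(1, 4))
            levels = np.sort(rng.uniform(0, 100, size=n_steps + 1))[::-1]
            bounds = np.sort(rng.choice(np.arange(2, n - 1), size=n_steps, replace=False))
            y = np.empty(n)
            prev = 0
            for lev, b in zip(levels, list(bounds) + [n]):
                y[prev:b] = lev
                prev = b
            y += rng.normal(0, 0.01, size=n)

            splits = _step_split_indices(y)
            if not splits:
                continue
            # oracle: best single split via cumulative sums
            c1 = np.cumsum(y)
            c2 = np.cumsum(y**2)
            best_s, best_sse = None, np.inf
            for s in range(2, n - 1):
                sse_l = c2[s - 1] - c1[s - 1] ** 2 / s
                sse_r = (c2[-1] - c2[s - 1]) - (c1[-1] - c1[s - 1]) ** 2 / (n - s)
                if sse_l + sse_r < best_sse:
                    best_sse, best_s = sse_l + sse_r, s
            top = min(
                splits,
                key=lambda s: sum((y[:s] - y[:s].mean()) ** 2)
                + sum((y[s:] - y[s:].mean()) ** 2),
            )
            assert top == best_s


class TestScanResolutions:
    def test_bridge_instance_kin_values(self, ):
        g = _two_cliques_bridge(4)
        m = g.number_of_edges()
        scan = scan_resolutions(g, grid=[0.1, 0.5, 1.0, 1.5, 2.0], seed=0)
        # one cluster keeps all m links; the two-clique split loses the bridge
        assert scan.kin[0] in (m, m - 1)
        assert np.all(scan.kin <= m)

    def test_determinism(self):
        g = _two_cliques_bridge(5)
        a = scan_resolutions(g, seed=3)
        b = scan_resolutions(g, seed=3)
        assert np.array_equal(a.kin, b.kin)
        for pa, pb in zip(a.clusterings, b.clusterings):
            assert sorted(map(sorted, pa)) == sorted(map(sorted, pb))

    def test_rejects_bad_grid(self):
        g = _two_cliques_bridge(4)
        with pytest.raises(ValueError, match="at least 5"):
            scan_resolutions(g, grid=[0.5, 1.0])
        with pytest.raises(ValueError, match="\\(0, 2\\]"):
            scan_resolutions(g, grid=[0.5, 1.0, 1.5, 2.0, 2.5])


class TestAdaptSplit:
    def test_disconnected_cliques_recovered_for_any_grid(self, two_cliques):
        for grid in (default_gamma_grid(), [0.2, 0.6, 1.0, 1.4, 1.8]):
            result = adapt_split(two_cliques, grid=grid, seed=0)
            parts = sorted(map(sorted, result.partition))
            assert parts == [list(range(6)), list(range(6, 12))]

    def test_gamma_f_is_lower_median(self):
        scan_gammas = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        from msclust.adaptsplit import _lower_median

        assert _lower_median(scan_gammas) == 0.3
        assert _lower_median(np.array([0.1, 0.2])) == 0.1

    def test_two_gaussian_blocks_split_exactly(self):
        from msclust import ScenarioSpec, build_len, simulate_dataset
        from msclust.similarity import ExpressionMatrix, pearson_similarity

        spec = ScenarioSpec(
            "I", (25, 25), rho_in=0.8, sigma=0.2, n_features=300, seed=2
        )
        ds = simulate_dataset(spec)
        expr = ExpressionMatrix(
            ds.data.T, ds.sample_ids, [f"g{i}" for i in range(300)]
        )
        g = build_len(pearson_similarity(expr))
        if nx.number_connected_components(g) == 2:
            comps = sorted(map(sorted, nx.connected_components(g)))
        else:
            result = adapt_split(g, seed=0)
            comps = sorted(map(sorted, result.partition))
        assert comps == [list(range(25)), list(range(25, 50))]

    def test_same_seed_identical_result(self, two_cliques):
        two_cliques.add_edge(0, 6)
        a = adapt_split(two_cliques, seed=1)
        b = adapt_split(two_cliques, seed=1)
        assert a.gamma_f == b.gamma_f
        assert sorted(map(sorted, a.partition)) == sorted(map(sorted, b.partition))
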