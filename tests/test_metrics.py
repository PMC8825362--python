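"""Graph-metric correctness against brute-force and networkx oracles."""

import networkx as nx
import numpy as np
import pytest

from roinet import metrics

import oracles
from conftest import complete_graph, path_graph, ring_lattice, star_graph


class TestClosedForms:
    def test_complete_graph_identities(self):
        a = complete_graph(4)
        per, cp = metrics.clustering(a)
        assert cp == 1.0
        paths = metrics.shortest_paths(a)
        assert metrics.characteristic_path_length(paths) == 1.0
        assert metrics.global_efficiency(paths) == 1.0
        assert metrics.local_efficiency(a) == 1.0
        nm = metrics.nodal_metrics(a)
        assert np.all(nm.NBi == 0.0)
        assert np.all(nm.NEi == 1.0)

    def test_star_graph_identities(self):
        a = star_graph(5)
        _, cp = metrics.clustering(a)
        assert cp == 0.0
        assert metrics.local_efficiency(a) == 0.0
        nm = metrics.nodal_metrics(a)
        assert nm.NBi[0] == 1.0
        assert np.all(nm.NBi[1:] == 0.0)

    def test_path_graph_p4(self):
        a = path_graph(4)
        paths = metrics.shortest_paths(a)
        # ordered distances: 6 pairs at 1, 4 at 2, 2 at 3 -> mean 20/12
        assert metrics.characteristic_path_length(paths) == pytest.approx(5 / 3)
        assert metrics.global_efficiency(paths) == pytest.approx(13 / 18)
        nm = metrics.nodal_metrics(a)
        # inner node carries 2 of the 3 eligible ordered-pair groups
        assert nm.NBi[1] == pytest.approx(2 / 3)
        assert nm.NBi[2] == pytest.approx(2 / 3)
        assert np.all(nm.NBi[[0, 3]] == 0.0)

    def test_disconnected_pairs_conventions(self):
        # two disjoint edges: cross-component distances are infinite,
        # Lp over finite pairs is 1, efficiency counts them as zero
        a = np.zeros((4, 4), dtype=np.uint8)
        a[0, 1] = a[1, 0] = 1
        a[2, 3] = a[3, 2] = 1
        paths = metrics.shortest_paths(a)
        assert np.isinf(paths.distances[0, 2])
        assert metrics.characteristic_path_length(paths) == 1.0
        assert metrics.global_efficiency(paths) == pytest.approx(4 / 12)

    def test_empty_graph_rejected_for_path_length(self):
        paths = metrics.shortest_paths(np.zeros((4, 4), dtype=np.uint8))
        assert metrics.global_efficiency(paths) == 0.0
        with pytest.raises(ValueError, match="no edges"):
            metrics.characteristic_path_length(paths)


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(25))
    def test_small_graphs_match_bruteforce(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(3, 9))
        a = oracles.random_graph(rng, n, float(rng.uniform(0.2, 0.9)))
        dist, counts, _ = oracles.brute_path_stats(a)
        paths = metrics.shortest_paths(a)
        assert np.array_equal(paths.distances, dist)
        assert np.array_equal(paths.counts[np.isfinite(dist)],
                              counts[np.isfinite(dist)])
        per, cp = metrics.clustering(a)
        bper, bcp = oracles.brute_clustering(a)
        np.testing.assert_allclose(per, bper, atol=1e-12)
        nm = metrics.nodal_metrics(a)
        np.testing.assert_allclose(nm.NBi, oracles.brute_betweenness(a),
                                   atol=1e-12)
        np.testing.assert_allclose(nm.NEi,
                                   oracles.brute_nodal_efficiency(a),
                                   atol=1e-12)
        assert np.array_equal(nm.NDi, a.sum(axis=1))
        if a.sum() > 0:
            assert metrics.characteristic_path_length(paths) == \
                pytest.approx(oracles.brute_lp(a), abs=1e-12)
        assert metrics.global_efficiency(paths) == \
            pytest.approx(oracles.brute_eg(a), abs=1e-12)
        assert metrics.local_efficiency(a) == \
            pytest.approx(oracles.brute_eloc(a), abs=1e-12)

    def test_path_statistics_through_counts(self):
        rng = np.random.default_rng(5)
        a = oracles.random_graph(rng, 7, 0.4)
        _, _, through = oracles.brute_path_stats(a)
        paths = metrics.shortest_paths(a)
        for i in range(7):
            np.testing.assert_allclose(paths.through(i), through[i],
                                       atol=1e-12)

    def test_matches_networkx_on_moderate_graph(self, rng):
        """Independent library cross-check at a realistic size."""
        a = oracles.random_graph(rng, 40, 0.15)
        g = nx.from_numpy_array(a)
        nm = metrics.nodal_metrics(a)
        nx_btw = nx.betweenness_centrality(g, normalized=True)
        np.testing.assert_allclose(
            nm.NBi, [nx_btw[i] for i in range(40)], atol=1e-12)
        nx_clust = nx.clustering(g)
        per, _ = metrics.clustering(a)
        np.testing.assert_allclose(
            per, [nx_clust[i] for i in range(40)], atol=1e-12)
        paths = metrics.shortest_paths(a)
        assert metrics.global_efficiency(paths) == pytest.approx(
            nx.global_efficiency(g), abs=1e-12)


class TestStructuralProperties:
    def test_tree_betweenness_identity(self, rng):
        """On trees each pair has one shortest path, so the unnormalized
        betweenness total equals the sum of (path length - 1) over pairs."""
        for _ in range(5):
            n = int(rng.integers(4, 12))
            a = oracles.random_tree(rng, n)
            paths = metrics.shortest_paths(a)
            nm = metrics.nodal_metrics(a)
            unnorm = nm.NBi * (n - 1) * (n - 2)
            d = paths.distances
            iu = np.triu_indices(n, k=1)
            expected = 2 * (d[iu] - 1).sum()  # ordered pairs
            assert unnorm.sum() == pytest.approx(expected, abs=1e-9)

    def test_permutation_equivariance(self, rng):
        a = oracles.random_graph(rng, 15, 0.3)
        perm = rng.permutation(15)
        b = a[np.ix_(perm, perm)]
        nm_a = metrics.nodal_metrics(a)
        nm_b = metrics.nodal_metrics(b)
        np.testing.assert_allclose(nm_b.NBi, nm_a.NBi[perm], atol=1e-12)
        np.testing.assert_allclose(nm_b.NEi, nm_a.NEi[perm], atol=1e-12)
        assert metrics.local_efficiency(a) == pytest.approx(
            metrics.local_efficiency(b), abs=1e-12)

    def test_adding_edge_improves_connectivity(self, rng):
        for _ in range(5):
            a = oracles.random_graph(rng, 12, 0.25)
            missing = np.argwhere(np.triu(a == 0, k=1))
            missing = [e for e in missing if e[0] != e[1]]
            if not missing:
                continue
            i, j = missing[int(rng.integers(len(missing)))]
            b = a.copy()
            b[i, j] = b[j, i] = 1
            pa, pb = metrics.shortest_paths(a), metrics.shortest_paths(b)
            assert metrics.global_efficiency(pb) >= \
                metrics.global_efficiency(pa)
            if np.isfinite(pa.distances[~np.eye(12, dtype=bool)]).all():
                assert metrics.characteristic_path_length(pb) <= \
                    metrics.characteristic_path_length(pa)


class TestRandomReference:
    def test_swap_preserves_degree_sequence(self, rng):
        a = oracles.random_graph(rng, 20, 0.3)
        swapped = metrics.double_edge_swap(a, n_swaps=200, rng=rng)
        assert np.array_equal(swapped.sum(axis=1), a.sum(axis=1))
        assert np.array_equal(swapped, swapped.T)
        assert np.all(np.diag(swapped) == 0)

    def test_ensemble_seeded_determinism(self, rng):
        a = oracles.random_graph(rng, 20, 0.25)
        r1 = metrics.random_reference_ensemble(a, n_random=10, seed=42)
        r2 = metrics.random_reference_ensemble(a, n_random=10, seed=42)
        assert r1 == r2
        r3 = metrics.random_reference_ensemble(a, n_random=10, seed=43)
        assert r1 != r3

    def test_complete_graph_returns_own_values(self):
        a = complete_graph(6)
        with pytest.warns(UserWarning, match="complete"):
            cr, lr = metrics.random_reference_ensemble(a, n_random=5, seed=0)
        assert cr == 1.0
        assert lr == 1.0

    def test_too_few_edges_rejected(self):
        a = np.zeros((5, 5), dtype=np.uint8)
        a[0, 1] = a[1, 0] = 1
        with pytest.raises(ValueError, match="2 edges"):
            metrics.random_reference_ensemble(a, n_random=3, seed=0)


class TestSmallWorld:
    def test_sigma_is_gamma_over_lambda(self, rng):
        a = oracles.random_graph(rng, 25, 0.3)
        gm = metrics.small_world(a, n_random=10, seed=9)
        assert gm.sigma == pytest.approx(gm.gamma / gm.lambda_, abs=1e-12)
        assert 0 <= gm.Cp <= 1
        assert 0 <= gm.Eg <= 1
        assert 0 <= gm.Eloc <= 1

    def test_ring_lattice_is_clustered(self):
        """A regular lattice has far more triangles than its rewired
        references: gamma must exceed one."""
        a = ring_lattice(20, 4)
        gm = metrics.small_world(a, n_random=20, seed=3)
        assert gm.gamma > 1.0

    def test_self_reference_identity(self, rng):
        """If the reference ensemble were the graph itself the ratios are 1;
        verified by computing Cp/Lp directly."""
        a = oracles.random_graph(rng, 15, 0.4)
        _, cp = metrics.clustering(a)
        lp = metrics.characteristic_path_length(metrics.shortest_paths(a))
        assert cp / cp == 1.0 and lp / lp == 1.0


class TestHubs:
    def test_single_outlier_hub(self):
        values = np.array([1.0, 1.0, 1.0, 1.0, 10.0])
        hs = metrics.identify_hubs(values, "NDi")
        # mean 2.8, sample SD ~4.02 -> threshold ~6.82
        assert hs.hub_nodes == (4,)
        assert hs.threshold == pytest.approx(2.8 + values.std(ddof=1))

    def test_constant_values_give_empty_hub_set(self):
        assert metrics.identify_hubs(np.ones(10)).hub_nodes == ()

    def test_linear_ramp_matches_bruteforce_filter(self):
        values = np.linspace(0.0, 1.0, 90)
        hs = metrics.identify_hubs(values)
        thr = values.mean() + values.std(ddof=1)
        expected = tuple(i for i in range(90) if values[i] > thr)
        assert hs.hub_nodes == expected
        assert all(values[i] > hs.threshold for i in hs.hub_nodes)


class TestMetricTables:
    def test_table_shapes_and_determinism(self, small_cohort):
        from roinet import connectivity

        records, _ = small_cohort
        stacks = [
            connectivity.build_graph_stack(
                connectivity.pearson_matrix(r),
                sparsities=(0.1, 0.2, 0.3))
            for r in records[:3]
        ]
        nodal = metrics.nodal_metric_table(stacks)
        assert len(nodal) == 3 * 3 * 30
        assert set(nodal.columns) >= {"subject_id", "sparsity", "node",
                                      "NDi", "NEi", "NBi"}
        g1 = metrics.global_metric_table(stacks, n_random=5, seed=1)
        g2 = metrics.global_metric_table(stacks, n_random=5, seed=1)
        assert g1.equals(g2)
        assert len(g1) == 3 * 3
        np.testing.assert_allclose(
            g1["sigma"], g1["gamma"] / g1["lambda"], atol=1e-12)
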