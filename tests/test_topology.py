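import itertools
import math

import networkx as nx
import numpy as np
import pytest

from netlab import topology


class TestDegreeDistribution:
    def test_triangle(self, triangle):
        dd = topology.degree_distribution(triangle)
        assert dd.counts == {2: 3} and dd.n_total == 3

    def test_star_and_probability_sum(self):
        dd = topology.degree_distribution(nx.star_graph(5))
        assert dd.counts == {5: 1, 1: 5}
        assert sum(dd.probabilities().values()) == pytest.approx(1.0)

    def test_zero_degree_nodes_counted(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_node("X")
        assert topology.degree_distribution(g).counts == {1: 2, 0: 1}


class TestPowerLawFit:
    def test_exact_log_linear_data(self):
        counts = {k: 100.0 * k ** -2.0 for k in range(1, 21)}
        fit = topology.fit_power_law(topology.DegreeDistribution(counts, 100))
        assert fit.gamma == pytest.approx(2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.prefactor == pytest.approx(100.0, rel=1e-9)

    def test_rounded_scale_free_table(self):
        # integer-rounded counts from a gamma = 1.38 law, checked against a
        # hand-rolled closed-form OLS on the same points
        ks = np.arange(1, 51)
        counts = np.round(335.4 * ks ** -1.38).astype(int)
        dd = topology.DegreeDistribution(
            {int(k): int(c) for k, c in zip(ks, counts) if c > 0}, int(counts.sum()))
        fit = topology.fit_power_law(dd)
        x = np.log10(ks[counts > 0])
        y = np.log10(counts[counts > 0])
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert fit.gamma == pytest.approx(-slope, abs=1e-12)
        assert abs(fit.gamma - 1.38) < 0.05

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            topology.fit_power_law(topology.DegreeDistribution({1: 5, 2: 3}, 8))

    def test_zero_degree_excluded_from_fit(self):
        counts = {0: 7, **{k: 100.0 * k ** -1.5 for k in range(1, 11)}}
        fit = topology.fit_power_law(topology.DegreeDistribution(counts, 100))
        assert fit.gamma == pytest.approx(1.5, abs=1e-12)
        assert fit.n_points == 10


def brute_force_local_clustering(g, node):
    nbrs = list(g.neighbors(node))
    if len(nbrs) < 2:
        return 0.0
    links = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
    return links / (len(nbrs) * (len(nbrs) - 1) / 2)


class TestClustering:
    def test_triangle_vertex(self, triangle):
        assert topology.local_clustering(triangle, "A") == 1.0

    def test_star_center(self):
        assert topology.local_clustering(nx.star_graph(5), 0) == 0.0

    def test_unknown_node_errors(self, triangle):
        with pytest.raises(ValueError):
            topology.local_clustering(triangle, "Z")

    def test_matches_triple_enumeration(self):
        g = nx.gnp_random_graph(20, 0.25, seed=5)
        for node in g:
            assert topology.local_clustering(g, node) == pytest.approx(
                brute_force_local_clustering(g, node))

    def test_complete_graph_global(self):
        rep = topology.global_clustering(nx.complete_graph(5))
        assert rep.global_coefficient == 1.0

    def test_path_graph_global(self):
        rep = topology.global_clustering(nx.path_graph(3))
        assert rep.global_coefficient == 0.0

    def test_tree_clusters_to_zero(self):
        rep = topology.global_clustering(nx.balanced_tree(2, 4))
        assert rep.global_coefficient == 0.0

    def test_coefficients_bounded(self, fixture_network):
        rep = topology.global_clustering(fixture_network)
        assert all(0.0 <= c <= 1.0 for c in rep.per_node.values())

    def test_er_global_clustering_near_p(self):
        # mean-of-nodes clustering on G(n, p) concentrates on p
        p = 0.02
        values = [topology.global_clustering(
            nx.gnp_random_graph(400, p, seed=s)).global_coefficient
            for s in range(20)]
        se = np.std(values, ddof=1) / math.sqrt(len(values))
        assert abs(np.mean(values) - p) < 3 * se


class TestPathStats:
    def test_complete_graph(self):
        stats = topology.path_length_stats(nx.complete_graph(4))
        assert stats.histogram == {1: 6} and stats.mean == 1.0

    def test_path_graph_enumeration(self):
        stats = topology.path_length_stats(nx.path_graph(4))
        assert stats.histogram == {1: 3, 2: 2, 3: 1}
        assert stats.mean == pytest.approx(10 / 6)
        assert stats.max == 3

    def test_pair_count_sums_over_components(self):
        g = nx.disjoint_union(nx.path_graph(4), nx.complete_graph(5))
        stats = topology.path_length_stats(g)
        assert sum(stats.histogram.values()) == math.comb(4, 2) + math.comb(5, 2)

    def test_edgeless_errors(self):
        g = nx.Graph()
        g.add_nodes_from("AB")
        with pytest.raises(ValueError):
            topology.path_length_stats(g)


def union_find_components(g):
    parent = {n: n for n in g}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in g.edges():
        parent[find(a)] = find(b)
    groups = {}
    for n in g:
        groups.setdefault(find(n), set()).add(n)
    return {frozenset(s) for s in groups.values()}


class TestComponents:
    def test_two_triangles(self):
        g = nx.disjoint_union(nx.cycle_graph(3), nx.cycle_graph(3))
        rep = topology.connected_components(g)
        assert [len(c) for c in rep.components] == [3, 3]

    def test_isolate_listed(self, triangle):
        triangle.add_node("X")
        rep = topology.connected_components(triangle)
        assert rep.isolates == frozenset({"X"})

    def test_matches_union_find(self):
        g = nx.gnp_random_graph(60, 0.03, seed=2)
        rep = topology.connected_components(g)
        assert set(rep.components) == union_find_components(g)


class TestHubs:
    def test_star_center_both_methods(self):
        g = nx.star_graph(5)
        for method in ("top_fraction", "degree_gap"):
            rep = topology.identify_hubs(g, method, 0.2)
            assert rep.hubs == frozenset({0})

    def test_bad_fraction_errors(self):
        with pytest.raises(ValueError):
            topology.identify_hubs(nx.star_graph(3), "top_fraction", 1.5)

    def test_published_degree_sequence_tiers(self):
        # degree-gap scan recovers the 4 + 4 tiered hub structure of a
        # heavy-tailed sequence headed 134, 110, 96, 77, 53, 45, 38, 35
        seq = [134, 110, 96, 77, 53, 45, 38, 35,
               15, 14, 13, 12, 11, 10] + [4] * 300 + [1] * 463
        g = nx.havel_hakimi_graph(seq)
        rep = topology.identify_hubs(g, "degree_gap", 0.1)
        degs = dict(g.degree())
        assert sorted((degs[h] for h in rep.hubs), reverse=True) == [134, 110, 96, 77]
        assert sorted((degs[h] for h in rep.second_tier), reverse=True) == [53, 45, 38, 35]

    def test_bimodal_blocks(self):
        # 6 nodes of degree ~50 vs 44 nodes of low degree
        g = nx.complete_graph(6)          # block nodes interconnected
        for i in range(6):
            for j in range(45):
                g.add_edge(i, f"leaf{i}_{j}")
        rep = topology.identify_hubs(g, "degree_gap", 0.2)
        assert rep.hubs == frozenset(range(6))


class TestDegreeShare:
    def test_degree_sum_identity(self, fixture_network):
        degrees = [d for _, d in fixture_network.degree()]
        assert sum(degrees) == 2 * fixture_network.number_of_edges()
        assert topology.degree_share(degrees, fixture_network.number_of_edges()) \
            == pytest.approx(200.0)
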