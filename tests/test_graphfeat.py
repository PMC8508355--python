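import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ki67topo import graphfeat
from ki67topo.datatypes import CellPattern

from conftest import make_pattern
import oracles


def graph_from_adj(adj):
    g = nx.Graph()
    g.add_nodes_from(range(len(adj)))
    g.add_edges_from(zip(*np.nonzero(np.triu(adj))))
    return g


class TestBuildGraph:
    def test_collinear_threshold_25(self):
        pat = make_pattern([(0, 0), (20, 0), (40, 0)])
        g = graphfeat.build_graph(pat, 25)
        assert sorted(g.edges()) == [(0, 1), (1, 2)]

    def test_collinear_threshold_50(self):
        pat = make_pattern([(0, 0), (20, 0), (40, 0)])
        g = graphfeat.build_graph(pat, 50)
        assert g.number_of_edges() == 3

    def test_closed_inequality(self):
        pat = make_pattern([(0, 0), (25, 0)])
        assert graphfeat.build_graph(pat, 25).number_of_edges() == 1

    def test_matches_bruteforce(self, rng):
        pts = rng.uniform(0, 500, size=(200, 2))
        pat = make_pattern(pts, window=(500, 500))
        g = graphfeat.build_graph(pat, 50)
        expected = {
            (i, j)
            for i in range(200)
            for j in range(i + 1, 200)
            if np.hypot(*(pts[i] - pts[j])) <= 50
        }
        assert {tuple(sorted(e)) for e in g.edges()} == expected

    def test_empty_pattern(self):
        g = graphfeat.build_graph(make_pattern(np.empty((0, 2))), 25)
        assert g.number_of_nodes() == 0

    def test_edges_monotone_in_threshold(self, rng):
        pts = rng.uniform(0, 300, size=(80, 2))
        pat = make_pattern(pts, window=(300, 300))
        counts = [graphfeat.build_graph(pat, t).number_of_edges() for t in (25, 50, 75)]
        assert counts == sorted(counts)


class TestLocalMetrics:
    def test_triangle_clustering(self):
        g = graph_from_adj(np.ones((3, 3), int) - np.eye(3, dtype=int))
        loc = graphfeat.local_metrics(g)
        assert np.allclose(loc["clustering"], 1.0)

    def test_star_betweenness(self):
        g = nx.star_graph(4)
        loc = graphfeat.local_metrics(g)
        assert loc["betweenness"][0] == pytest.approx(6.0)
        assert np.allclose(loc["betweenness"][1:], 0.0)

    def test_isolated_node_conventions(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1, 2])
        g.add_edge(1, 2)
        loc = graphfeat.local_metrics(g)
        for m in ("degree", "clustering", "local_efficiency", "eigenvector",
                  "closeness", "betweenness", "harmonic", "eccentricity"):
            assert loc[m][0] == 0.0, m

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        adj = oracles.random_adjacency(n, rng.uniform(0.2, 0.8), rng)
        g = graph_from_adj(adj)
        loc = graphfeat.local_metrics(g)
        expected = {
            "degree": oracles.degree(adj),
            "clustering": oracles.clustering(adj),
            "local_efficiency": oracles.local_efficiency(adj),
            "eigenvector": oracles.eigenvector_centrality(adj),
            "closeness": oracles.closeness(adj),
            "betweenness": oracles.betweenness(adj),
            "harmonic": oracles.harmonic(adj),
            "eccentricity": oracles.eccentricity(adj),
            "pagerank": oracles.pagerank(adj),
        }
        for m, exp in expected.items():
            assert np.allclose(loc[m], exp, atol=1e-9), m


class TestGlobalMetrics:
    def test_complete_graph(self):
        g = nx.complete_graph(5)
        glo = graphfeat.global_metrics(g)
        assert glo["density"] == pytest.approx(1.0)
        assert glo["global_efficiency"] == pytest.approx(1.0)

    def test_two_disconnected_edges_efficiency(self):
        g = nx.Graph([(0, 1), (2, 3)])
        glo = graphfeat.global_metrics(g)
        # 4 reachable ordered pairs at distance 1 out of 12 ordered pairs
        assert glo["global_efficiency"] == pytest.approx(4.0 / 12.0)

    def test_tiny_graph_conventions(self):
        g = nx.Graph()
        g.add_node(0)
        glo = graphfeat.global_metrics(g)
        assert list(glo.values()) == [0.0, 0.0, 0.0]

    def test_regular_ring_assortativity_convention(self):
        # all degrees equal: Pearson correlation undefined -> 0
        g = nx.cycle_graph(8)
        assert graphfeat.global_metrics(g)["assortativity"] == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(2, 11))
        adj = oracles.random_adjacency(n, rng.uniform(0.2, 0.8), rng)
        glo = graphfeat.global_metrics(graph_from_adj(adj))
        assert glo["density"] == pytest.approx(oracles.graph_density(adj), abs=1e-9)
        assert glo["global_efficiency"] == pytest.approx(oracles.efficiency_of(adj), abs=1e-9)
        assert glo["assortativity"] == pytest.approx(oracles.assortativity(adj), abs=1e-9)


class TestSummarize:
    def test_constant_list(self):
        s = graphfeat.summarize([2.0, 2.0, 2.0])
        assert s["amean"] == s["gmean"] == s["hmean"] == 2.0
        assert s["std"] == s["range"] == 0.0
        assert s["skew"] == s["kurt"] == 0.0
        assert s["m2"] == s["m3"] == s["m4"] == 0.0

    def test_1234(self):
        s = graphfeat.summarize([1, 2, 3, 4])
        assert s["amean"] == pytest.approx(2.5)
        assert s["q2"] == pytest.approx(2.5)
        assert s["range"] == pytest.approx(3.0)
        assert s["q1"] == pytest.approx(1.75)  # linear-interpolation quartile
        assert s["q3"] == pytest.approx(3.25)

    def test_zero_value_convention(self):
        s = graphfeat.summarize([0.0, 1.0, 2.0])
        assert s["gmean"] == 0.0
        assert s["hmean"] == 0.0

    def test_cardinality_and_order(self):
        s = graphfeat.summarize([1.0, 5.0, 2.0])
        assert list(s.keys()) == list(graphfeat.SUMMARY_STATS)
        assert len(s) == 16

    def test_empty_warns_and_zeros(self):
        with pytest.warns(UserWarning):
            s = graphfeat.summarize([])
        assert all(v == 0.0 for v in s.values())

    def test_quartile_ordering_random(self, rng):
        v = rng.normal(size=37)
        s = graphfeat.summarize(v)
        assert s["min"] <= s["q1"] <= s["q2"] <= s["q3"] <= s["max"]

    def test_mode_tie_breaks_smallest(self):
        assert graphfeat.summarize([3.0, 3.0, 1.0, 1.0, 2.0])["mode"] == 1.0


class TestFeatureBlock:
    def test_block_length_441(self, small_pattern):
        block = graphfeat.graph_feature_block(small_pattern)
        assert len(block) == 441

    def test_names_match_values(self, small_pattern):
        block = graphfeat.graph_feature_block(small_pattern)
        assert list(block.keys()) == graphfeat.graph_feature_names()

    def test_per_threshold_composition(self):
        names = graphfeat.graph_feature_names()
        per25 = [n for n in names if n.startswith("g25_")]
        assert len(per25) == 9 * 16 + 3 == 147

    def test_empty_pattern_zeros(self):
        with pytest.warns(UserWarning):
            block = graphfeat.graph_feature_block(make_pattern(np.empty((0, 2))))
        assert len(block) == 441
        assert all(v == 0.0 for v in block.values())

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(100, 400, size=(70, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + np.array([40.0, 25.0])
        b1 = graphfeat.graph_feature_block(make_pattern(pts, window=(600, 600)))
        b2 = graphfeat.graph_feature_block(make_pattern(moved, window=(600, 600)))
        for k in b1:
            assert b1[k] == pytest.approx(b2[k], rel=1e-9, abs=1e-8), k


class TestDisplayTransform:
    def test_constant(self):
        assert np.allclose(graphfeat.eigcentrality_display_transform([1, 1, 1]), 0.0)

    def test_powers_of_two(self):
        out = graphfeat.eigcentrality_display_transform([0.25, 0.5, 1.0])
        assert np.allclose(out, [0.0, 1.0, 2.0])

    def test_min_is_zero(self, rng):
        out = graphfeat.eigcentrality_display_transform(rng.uniform(0.1, 5.0, 20))
        assert out.min() == pytest.approx(0.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            graphfeat.eigcentrality_display_transform([0.0, 1.0])


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=1, max_size=40))
def test_summary_bounds_property(values):
    s = graphfeat.summarize(values)
    assert s["min"] <= s["amean"] <= s["max"]
    assert s["range"] == pytest.approx(s["max"] - s["min"])
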