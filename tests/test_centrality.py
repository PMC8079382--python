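import math
from fractions import Fraction

import numpy as np
import pytest

from conftest import make_graph, random_connected_graph
from oracles import brute_force_betweenness, dense_eigenvector
from tagnet.centrality import (
    betweenness_centrality,
    degree_and_strength,
    edge_betweenness,
    eigenvector_centrality,
)
from tagnet.errors import ConfigError, ConvergenceError, DataError
from tagnet.graph import HashtagGraph


class TestEigenvector:
    def test_triangle_uniform(self):
        g = make_graph([("a", "b"), ("a", "c"), ("b", "c")])
        sc = eigenvector_centrality(g, tolerance=1e-12)
        assert all(v == pytest.approx(1.0, abs=1e-10) for v in sc.node_scores.values())

    def test_star_closed_form(self):
        g = make_graph([("c", "a"), ("c", "b"), ("c", "d")])
        sc = eigenvector_centrality(g, tolerance=1e-12, max_iter=10000)
        assert sc.node_scores["c"] == pytest.approx(1.0)
        for leaf in "abd":
            assert sc.node_scores[leaf] == pytest.approx(1 / math.sqrt(3), abs=1e-9)

    def test_matches_dense_oracle(self, rng):
        for _ in range(10):
            g = random_connected_graph(rng, n_max=30)
            sc = eigenvector_centrality(g, tolerance=1e-13, max_iter=100000)
            oracle = dense_eigenvector(g)
            for v in g.nodes:
                assert sc.node_scores[v] == pytest.approx(oracle[v], abs=1e-8)

    def test_max_is_exactly_one(self, rng):
        g = random_connected_graph(rng)
        sc = eigenvector_centrality(g)
        assert max(sc.node_scores.values()) == 1.0

    def test_start_vector_invariance(self, rng):
        g = random_connected_graph(rng, n_max=20)
        starts = [
            {v: float(rng.uniform(0.1, 2.0)) for v in g.nodes} for _ in range(2)
        ]
        results = [
            eigenvector_centrality(g, tolerance=1e-13, max_iter=100000, start=s)
            for s in starts
        ]
        for v in g.nodes:
            assert results[0].node_scores[v] == pytest.approx(
                results[1].node_scores[v], abs=1e-9
            )

    def test_disconnected_giant_component_scoring(self):
        g = make_graph([("a", "b"), ("a", "c"), ("b", "c"), ("x", "y")])
        with pytest.warns(UserWarning, match="components"):
            sc = eigenvector_centrality(g)
        assert sc.node_scores["x"] == 0.0 and sc.node_scores["y"] == 0.0
        assert sc.node_scores["a"] == pytest.approx(1.0)

    def test_regular_graph_uniform(self):
        # 4-cycle is 2-regular: uniform scores
        g = make_graph([("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")])
        sc = eigenvector_centrality(g, tolerance=1e-12, max_iter=10000)
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in sc.node_scores.values())

    def test_nonconvergence_raises(self):
        g = make_graph([("a", "b"), ("b", "c")])
        with pytest.raises(ConvergenceError):
            eigenvector_centrality(g, tolerance=1e-300, max_iter=2)

    def test_empty_graph_rejected(self):
        with pytest.raises(DataError):
            eigenvector_centrality(HashtagGraph("x"))


class TestNodeBetweenness:
    def test_p3(self):
        g = make_graph([("a", "b"), ("b", "c")])
        sc = betweenness_centrality(g, mode="unweighted")
        assert sc.node_scores == {"a": 0.0, "b": 1.0, "c": 0.0}
        assert sc.node_scores_normalized["b"] == 1.0

    def test_k4_all_zero(self):
        edges = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]
        sc = betweenness_centrality(make_graph(edges), mode="unweighted")
        assert all(v == 0.0 for v in sc.node_scores.values())

    def test_p4_normalized(self):
        g = make_graph([("a", "b"), ("b", "c"), ("c", "d")])
        sc = betweenness_centrality(g, mode="unweighted")
        assert sc.node_scores_normalized["b"] == pytest.approx(2 / 3)
        assert sc.node_scores_normalized["c"] == pytest.approx(2 / 3)

    def test_weights_reroute_paths(self):
        # a-b-c heavy vs direct a-c light: inverse-weight distance makes
        # the two-hop route shorter, so b lies on the a..c shortest path
        g = make_graph([("a", "b"), ("b", "c"), ("a", "c")], weights=[10, 10, 1])
        sc = betweenness_centrality(g, mode="inverse_weight")
        assert sc.node_scores["b"] == 1.0
        un = betweenness_centrality(g, mode="unweighted")
        assert un.node_scores["b"] == 0.0

    def test_zero_weight_rejected_in_inverse_mode(self):
        g = make_graph([("a", "b")])
        g.edges[("a", "b")] = 0.0
        g.nodes = {"a": 1, "b": 1}
        with pytest.raises(DataError):
            betweenness_centrality(g, mode="inverse_weight")

    def test_unknown_mode(self):
        with pytest.raises(ConfigError):
            betweenness_centrality(make_graph([("a", "b")]), mode="nope")


class TestEdgeBetweenness:
    def test_p3_edges(self):
        g = make_graph([("a", "b"), ("b", "c")])
        sc = edge_betweenness(g, mode="unweighted")
        assert sc.edge_scores == {("a", "b"): 2.0, ("b", "c"): 2.0}

    def test_bridge_between_triangles(self, two_clique_bridge):
        sc = edge_betweenness(two_clique_bridge, mode="unweighted")
        assert sc.edge_scores[("c", "d")] == pytest.approx(9.0)

    def test_cut_edge_lower_bound(self, rng):
        # a bridge's betweenness >= product of the two side sizes
        g = make_graph(
            [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("d", "e"), ("d", "f"),
             ("e", "f")]
        )
        sc = edge_betweenness(g, mode="unweighted")
        assert sc.edge_scores[("c", "d")] >= 3 * 3


class TestOracleEquality:
    @pytest.mark.parametrize("mode", ["unweighted", "inverse_weight"])
    def test_exact_match_small_er(self, mode, rng):
        for _ in range(10):
            g = random_connected_graph(rng, n_max=8)
            node_o, edge_o = brute_force_betweenness(g, mode)
            sc_n = betweenness_centrality(g, mode=mode, exact=True)
            sc_e = edge_betweenness(g, mode=mode, exact=True)
            assert sc_n.node_scores == node_o
            assert sc_e.edge_scores == edge_o


class TestRelabelInvariance:
    def test_all_measures(self, rng):
        g = random_connected_graph(rng, n_max=12)
        mapping = {v: f"z{v}" for v in g.nodes}
        g2 = HashtagGraph(
            "relabel",
            nodes={mapping[v]: f for v, f in g.nodes.items()},
            edges={
                tuple(sorted((mapping[u], mapping[v]))): w
                for (u, v), w in g.edges.items()
            },
        )
        for v in g.nodes:
            assert eigenvector_centrality(g, tolerance=1e-12).node_scores[v] == \
                pytest.approx(
                    eigenvector_centrality(g2, tolerance=1e-12).node_scores[mapping[v]],
                    abs=1e-9,
                )
            assert betweenness_centrality(g).node_scores[v] == pytest.approx(
                betweenness_centrality(g2).node_scores[mapping[v]]
            )


class TestDegreeStrength:
    def test_star(self):
        g = make_graph([("c", "a"), ("c", "b"), ("c", "d")])
        deg, stren = degree_and_strength(g)
        assert deg.node_scores["c"] == 3.0
        assert stren.node_scores["c"] == 3.0

    def test_isolated_node(self):
        g = make_graph([("a", "b")], extra_nodes=["z"])
        deg, stren = degree_and_strength(g)
        assert deg.node_scores["z"] == 0.0 and stren.node_scores["z"] == 0.0

    def test_strength_is_adjacency_row_sum(self, rng):
        g = random_connected_graph(rng, n_max=15)
        nodes = sorted(g.nodes)
        idx = {v: i for i, v in enumerate(nodes)}
        A = np.zeros((len(nodes), len(nodes)))
        for (u, v), w in g.edges.items():
            A[idx[u], idx[v]] = A[idx[v], idx[u]] = w
        _, stren = degree_and_strength(g)
        for v in nodes:
            assert stren.node_scores[v] == pytest.approx(A[idx[v]].sum())
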