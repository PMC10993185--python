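"""Structural variables: strength, WDC, uniformity, cuts, cliques."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazenet import (
    clique_stats,
    compute_metrics,
    cut_size,
    group_strength,
    maximal_cliques,
    normalized_cut_size,
    outgoing_weight_profile,
    strength,
    to_undirected,
    uniformity,
    weighted_degree_centrality,
)

from conftest import brute_force_maximal_cliques, make_network

weight_profiles = st.lists(st.floats(0.1, 1e4), min_size=1, max_size=12)


def random_network(rng, n_nodes=None, participant="r"):
    n = n_nodes or int(rng.integers(2, 9))
    nodes = [f"n{i}" for i in range(n)]
    edges = []
    for u, v in itertools.permutations(nodes, 2):
        if rng.random() < 0.4:
            edges.append((u, v, int(rng.integers(1, 20))))
    return make_network(edges, nodes=nodes, participant=participant)


class TestStrength:
    def test_sum_of_in_and_out(self, toy_network):
        # A: out 2 (A->B), in 1 (B->A); B: in 2, out 2
        assert strength(toy_network, "A") == 3
        assert strength(toy_network, "B") == 4
        assert strength(toy_network, "C") == 1

    def test_isolated_node(self):
        net = make_network([], nodes={"A"})
        assert strength(net, "A") == 0

    def test_shared_edge_symmetry(self):
        net = make_network([("A", "B", 2), ("B", "A", 1)])
        assert strength(net, "A") == strength(net, "B") == 3

    def test_unknown_node(self, toy_network):
        with pytest.raises(KeyError):
            strength(toy_network, "Z")


class TestGroupStrength:
    def test_default_counts_internal_edges_twice(self, toy_network):
        assert group_strength(toy_network, {"A", "B"}) == 7

    def test_exclude_internal_counts_only_boundary(self, toy_network):
        assert group_strength(toy_network, {"A", "B"}, exclude_internal=True) == 1

    def test_whole_network_is_twice_total_weight(self, toy_network):
        assert group_strength(toy_network, toy_network.nodes) == 2 * toy_network.total_weight

    def test_empty_group_rejected(self, toy_network):
        with pytest.raises(ValueError):
            group_strength(toy_network, set())


class TestWeightedDegreeCentrality:
    @pytest.mark.parametrize(
        "weights, expected",
        [
            ([1, 1, 1, 1], 4.0),
            ([1, 1, 2], 2.5),
            ([7], 1.0),
            ([5, 5], 2.0),
        ],
    )
    def test_analytic_values(self, weights, expected):
        assert weighted_degree_centrality(weights) == pytest.approx(expected)

    @given(weight_profiles)
    @settings(max_examples=300, deadline=None)
    def test_bounds_and_uniform_maximum(self, weights):
        """1 <= WDC <= DC, with WDC = DC exactly iff all weights equal."""
        wdc = weighted_degree_centrality(weights)
        dc = len(weights)
        assert 1.0 - 1e-9 <= wdc <= dc + 1e-9
        if len(set(weights)) == 1:
            assert wdc == pytest.approx(dc)

    @given(weight_profiles, st.floats(0.01, 100.0))
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, weights, c):
        assert weighted_degree_centrality([c * w for w in weights]) == pytest.approx(
            weighted_degree_centrality(weights), rel=1e-9
        )

    @given(weight_profiles, st.randoms(use_true_random=False))
    @settings(max_examples=100, deadline=None)
    def test_order_invariance(self, weights, rnd):
        shuffled = list(weights)
        rnd.shuffle(shuffled)
        assert weighted_degree_centrality(shuffled) == pytest.approx(
            weighted_degree_centrality(weights)
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            weighted_degree_centrality([])
        with pytest.raises(ValueError):
            weighted_degree_centrality([1.0, -2.0])

    def test_profile_extraction_sorted_ascending(self, toy_network):
        net = make_network([("B", "A", 3), ("B", "C", 1), ("B", "D", 2)])
        assert outgoing_weight_profile(net, "B") == [1.0, 2.0, 3.0]


class TestUniformity:
    def test_equal_weights_give_zero(self):
        assert uniformity(make_network([("A", "B", 2), ("B", "C", 2), ("C", "A", 2)])) == 0.0

    def test_two_edge_example(self):
        assert uniformity(make_network([("A", "B", 1), ("B", "A", 3)])) == pytest.approx(-1.0)

    def test_three_edge_example(self):
        net = make_network([("A", "B", 1), ("B", "C", 1), ("C", "A", 4)])
        assert uniformity(net) == pytest.approx(-3.0)

    def test_never_positive_on_random_networks(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            net = random_network(rng)
            if net.graph.number_of_edges() == 0:
                continue
            assert uniformity(net) <= 1e-12

    def test_concentration_decreases_uniformity(self):
        """Moving weight from a below-mean edge to an above-mean edge
        (mean fixed) strictly decreases U."""
        before = uniformity(make_network([("A", "B", 2), ("B", "C", 4)]))
        after = uniformity(make_network([("A", "B", 1), ("B", "C", 5)]))
        assert after < before

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            uniformity(make_network([], nodes={"A", "B"}))


class TestCutSize:
    def test_directed_example(self):
        net = make_network([("A", "B", 3), ("B", "C", 2)])
        assert cut_size(net, {"A"}, {"B", "C"}) == 3
        assert normalized_cut_size(net, {"A"}, {"B", "C"}) == pytest.approx(0.6)

    def test_both_directions_counted(self):
        net = make_network([("A", "B", 3), ("B", "A", 2)])
        assert cut_size(net, {"A"}, {"B"}) == 5

    def test_no_crossing_edges(self):
        net = make_network([("A", "B", 3)], nodes={"A", "B", "C", "D"})
        assert cut_size(net, {"C"}, {"D"}) == 0

    def test_fully_crossing_normalizes_to_one(self):
        net = make_network([("A", "B", 3), ("B", "A", 1)])
        assert normalized_cut_size(net, {"A"}, {"B"}) == pytest.approx(1.0)

    def test_partition_validation(self, toy_network):
        with pytest.raises(ValueError):
            cut_size(toy_network, {"A"}, {"A", "B"})
        with pytest.raises(ValueError):
            cut_size(toy_network, set(), {"B"})
        with pytest.raises(ValueError):
            cut_size(toy_network, {"A"}, {"Z"})

    def test_cut_conservation_on_random_partitions(self):
        """cut(S,T) + internal(S) + internal(T) = total weight whenever
        S and T cover all nodes."""
        rng = np.random.default_rng(11)
        for _ in range(1000):
            net = random_network(rng)
            nodes = sorted(net.nodes)
            mask = rng.random(len(nodes)) < 0.5
            s = {n for n, m in zip(nodes, mask) if m}
            t = set(nodes) - s
            if not s or not t:
                continue
            internal = lambda grp: sum(
                d["weight"] for u, v, d in net.graph.edges(data=True) if u in grp and v in grp
            )
            assert cut_size(net, s, t) + internal(s) + internal(t) == pytest.approx(
                net.total_weight
            )


class TestCliques:
    def test_triangle_plus_pendant(self):
        net = make_network([("A", "B", 1), ("B", "C", 1), ("A", "C", 1), ("C", "D", 1)])
        stats = clique_stats(to_undirected(net))
        assert set(stats.cliques) == {("A", "B", "C"), ("C", "D")}
        assert stats.count == 2
        assert stats.average_size == pytest.approx(2.5)

    def test_complete_graph_single_clique(self):
        edges = [(u, v, 1) for u, v in itertools.combinations("ABCD", 2)]
        stats = clique_stats(to_undirected(make_network(edges)))
        assert stats.cliques == (("A", "B", "C", "D"),)

    def test_edgeless_graph_gives_singletons(self):
        stats = clique_stats(to_undirected(make_network([], nodes={"A", "B", "C"})))
        assert stats.count == 3
        assert stats.average_size == 1.0
        assert stats.count_nontrivial == 0

    def test_directed_input_rejected(self, toy_network):
        with pytest.raises(TypeError, match="to_undirected"):
            maximal_cliques(toy_network)

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        """Clique enumeration agrees with brute-force subset search on
        random graphs of up to 8 nodes."""
        rng = np.random.default_rng(19)
        for _ in range(500):
            net = random_network(rng, n_nodes=int(rng.integers(2, 9)))
            u = to_undirected(net)
            assert maximal_cliques(u) == brute_force_maximal_cliques(u.graph)


class TestMetricsReport:
    def test_full_report_round_trips_to_json(self, tmp_path, toy_network):
        report = compute_metrics(
            toy_network,
            groups={"front": ["A", "B"]},
            partitions={"split": (["A"], ["B", "C"])},
        )
        assert report.node_strength == {"A": 3, "B": 4, "C": 1}
        assert report.group_strengths["front"] == 7
        assert report.cuts["split"]["cut_size"] == 3
        assert report.wdc["B"] == pytest.approx(2.0)  # outgoing [1, 1]
        path = tmp_path / "metrics.json"
        report.to_json(path)
        import json

        data = json.loads(path.read_text())
        assert data["parameters"]["groups"]["front"] == ["A", "B"]
        assert data["uniformity"] == pytest.approx(-0.5)  # weights [2,1,1], mean 4/3

    def test_determinism(self, toy_network):
        a = compute_metrics(toy_network).to_json()
        b = compute_metrics(toy_network).to_json()
        assert a == b
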