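"""Possible-world semantics of uncertain graphs: canonical edges, containment
probability, instance enumeration and connectivity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ubnet as ub
from conftest import random_network


edge_prob_maps = st.dictionaries(
    st.tuples(st.integers(0, 5), st.integers(0, 5)).filter(lambda e: e[0] < e[1]),
    st.floats(0.01, 1.0),
    max_size=8,
)


class TestCanonicalEdge:
    @pytest.mark.parametrize("pair, expected", [((3, 1), (1, 3)), ((1, 3), (1, 3))])
    def test_unordered_pair_is_canonicalized(self, pair, expected):
        assert ub.canonical_edge(*pair) == expected
        assert ub.canonical_edge(*pair[::-1]) == expected

    def test_self_loop_rejected_naming_node(self):
        with pytest.raises(ValueError, match="2"):
            ub.canonical_edge(2, 2)


class TestUncertainNetwork:
    def test_nonpositive_probabilities_become_non_edges(self):
        net = ub.UncertainNetwork([1, 2, 3], {(1, 2): 0.5, (1, 3): 0.0, (2, 3): -0.2})
        assert net.edges() == [(1, 2)]
        assert net.probability((1, 3)) == 0.0

    def test_probability_above_one_rejected(self):
        with pytest.raises(ValueError, match="> 1"):
            ub.UncertainNetwork([1, 2], {(1, 2): 1.2})

    def test_edge_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ub.UncertainNetwork([1, 2], {(1, 9): 0.4})

    def test_symmetric_storage(self):
        net = ub.UncertainNetwork([1, 2], {(2, 1): 0.7})
        assert net.probability((1, 2)) == net.probability((2, 1)) == 0.7


class TestSubgraphProbability:
    def test_product_of_edge_probabilities(self, two_edge_net):
        g = ub.SubgraphPattern([(1, 2), (2, 3)])
        assert ub.subgraph_probability(two_edge_net, g) == pytest.approx(0.20)

    def test_missing_edge_gives_zero(self, two_edge_net):
        g = ub.SubgraphPattern([(1, 3)])
        assert ub.subgraph_probability(two_edge_net, g) == 0.0

    def test_certain_graph_limit_is_one(self):
        net = ub.UncertainNetwork([1, 2, 3], {(1, 2): 1.0, (2, 3): 1.0})
        g = ub.SubgraphPattern([(1, 2), (2, 3)])
        assert ub.subgraph_probability(net, g) == 1.0

    def test_adding_edges_never_increases_probability(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            net = random_network(rng)
            edges = net.edges()
            if len(edges) < 2:
                continue
            # grow a connected pattern one edge at a time; probability must
            # be non-increasing since every factor is <= 1
            sub = ub.SubgraphPattern([edges[0]])
            p_prev = ub.subgraph_probability(net, sub)
            nodes = set(edges[0])
            for e in edges[1:]:
                if not nodes & set(e):
                    continue
                sub = ub.SubgraphPattern(list(sub.edges) + [e])
                nodes |= set(e)
                p = ub.subgraph_probability(net, sub)
                assert p <= p_prev + 1e-12
                p_prev = p


class TestInstances:
    def test_single_world_probability(self, two_edge_net):
        assert ub.instance_probability(two_edge_net, [(1, 2)]) == pytest.approx(0.30)

    def test_symmetric_half_probabilities(self):
        net = ub.UncertainNetwork([1, 2, 3], {(1, 2): 0.5, (2, 3): 0.5})
        for included in ([], [(1, 2)], [(2, 3)], [(1, 2), (2, 3)]):
            assert ub.instance_probability(net, included) == pytest.approx(0.25)

    def test_all_edges_certain_graph(self):
        net = ub.UncertainNetwork([1, 2, 3], {(1, 2): 1.0, (2, 3): 1.0})
        assert ub.instance_probability(net, net.edges()) == 1.0

    def test_foreign_edge_rejected(self, two_edge_net):
        with pytest.raises(ValueError, match="not in the network"):
            ub.instance_probability(two_edge_net, [(1, 3)])

    def test_enumeration_counts(self, two_edge_net):
        assert len(ub.enumerate_instances(two_edge_net)) == 4
        empty = ub.UncertainNetwork([1, 2], {})
        (only,) = ub.enumerate_instances(empty)
        assert only.probability == 1.0 and not only.edges

    def test_enumeration_guard(self):
        probs = {(i, j): 0.5 for i in range(7) for j in range(i + 1, 7)}
        net = ub.UncertainNetwork(range(7), probs)
        with pytest.raises(ValueError, match="20"):
            ub.enumerate_instances(net, max_edges=20)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(edge_prob_maps)
    def test_world_probabilities_sum_to_one_property(self, probs):
        net = ub.UncertainNetwork(range(6), probs)
        total = sum(i.probability for i in ub.enumerate_instances(net))
        assert math.isclose(total, 1.0, abs_tol=1e-9)

    def test_world_probabilities_sum_to_one(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            net = random_network(rng, n_nodes=5)
            if net.n_edges > 8:
                continue
            total = sum(i.probability for i in ub.enumerate_instances(net))
            assert math.isclose(total, 1.0, abs_tol=1e-9)

    def test_containment_equals_marginal_over_worlds(self):
        """Eq-4 containment equals summing Eq-1 world probabilities over
        worlds that include the pattern."""
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 20:
            net = random_network(rng, n_nodes=5)
            edges = net.edges()
            if not 2 <= len(edges) <= 8:
                continue
            k = rng.integers(1, min(3, len(edges)) + 1)
            chosen = [edges[i] for i in rng.choice(len(edges), size=k, replace=False)]
            try:
                g = ub.SubgraphPattern(chosen)
            except ValueError:
                continue  # disconnected draw
            marginal = sum(
                inst.probability
                for inst in ub.enumerate_instances(net)
                if set(g.edges) <= inst.edges
            )
            assert ub.subgraph_probability(net, g) == pytest.approx(marginal, abs=1e-9)
            checked += 1


class TestConnectivity:
    @pytest.mark.parametrize(
        "edges, expected",
        [
            ([(1, 2), (2, 3)], True),
            ([(1, 2), (3, 4)], False),
            ([(1, 2), (2, 3), (1, 3)], True),
        ],
    )
    def test_examples(self, edges, expected):
        assert ub.is_connected(edges) is expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ub.is_connected([])

    def test_pattern_construction_requires_connectivity(self):
        with pytest.raises(ValueError, match="connected"):
            ub.SubgraphPattern([(1, 2), (3, 4)])


class TestCohort:
    def test_mismatched_universe_rejected(self):
        a = ub.UncertainNetwork([1, 2], {(1, 2): 0.5})
        b = ub.UncertainNetwork([1, 3], {(1, 3): 0.5})
        with pytest.raises(ValueError, match="universe"):
            ub.Cohort([a, b], [1, -1])

    def test_bad_labels_rejected(self):
        a = ub.UncertainNetwork([1, 2], {(1, 2): 0.5})
        with pytest.raises(ValueError, match="labels"):
            ub.Cohort([a, a], [1, 2])

    def test_group_split(self):
        a = ub.UncertainNetwork([1, 2], {(1, 2): 0.5})
        b = ub.UncertainNetwork([1, 2], {(1, 2): 0.9})
        cohort = ub.Cohort([a, b], [1, -1])
        assert cohort.positives == [a] and cohort.negatives == [b]
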