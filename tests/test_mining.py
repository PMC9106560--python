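"""Frequent-subgraph mining: expected support, frequent edges, pattern
growth, the unFEPG miner and its brute-force oracle."""

import numpy as np
import pytest

import ubnet as ub
from ubnet.mining import increasing_prefixes_connected
from conftest import random_cohort


class TestExpectedSupport:
    def test_mean_of_containment_probabilities(self):
        a = ub.UncertainNetwork([1, 2], {(1, 2): 0.2})
        b = ub.UncertainNetwork([1, 2], {(1, 2): 0.4})
        g = ub.SubgraphPattern([(1, 2)])
        assert ub.expected_support(g, [a, b]) == pytest.approx(0.3)

    def test_absent_everywhere_is_zero(self):
        a = ub.UncertainNetwork([1, 2, 3], {(1, 2): 0.9})
        g = ub.SubgraphPattern([(2, 3)])
        assert ub.expected_support(g, [a, a]) == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ub.expected_support(ub.SubgraphPattern([(1, 2)]), [])

    def test_anti_monotone_in_the_pattern(self):
        rng = np.random.default_rng(8)
        pairs = 0
        while pairs < 100:
            nets = random_cohort(int(rng.integers(1e6)), n_nets=6)
            union = sorted({e for n in nets for e in n.edge_prob})
            if len(union) < 3:
                continue
            idx = rng.choice(len(union), size=3, replace=False)
            try:
                sup = ub.SubgraphPattern([union[i] for i in idx])
                sub = ub.SubgraphPattern(list(sup.edges)[:2])
            except ValueError:
                continue
            assert ub.expected_support(sub, nets) >= ub.expected_support(sup, nets) - 1e-12
            pairs += 1


class TestFrequentEdges:
    def test_threshold_is_inclusive(self):
        nets = [ub.UncertainNetwork([1, 2], {(1, 2): 0.5}) for _ in range(2)]
        M = ub.frequent_edges(nets, 0.5)
        assert M.edges == [(1, 2)] and M.esup == [pytest.approx(0.5)]

    def test_edge_below_threshold_excluded(self):
        a = ub.UncertainNetwork([1, 2], {(1, 2): 0.3})
        b = ub.UncertainNetwork([1, 2], {})
        assert ub.frequent_edges([a, b], 0.25).edges == []  # esup 0.15

    def test_minsup_one_requires_certain_everywhere(self):
        a = ub.UncertainNetwork([1, 2, 3], {(1, 2): 1.0, (2, 3): 0.99})
        assert ub.frequent_edges([a], 1.0).edges == [(1, 2)]


class TestGrowPatterns:
    def M(self):
        return ub.FrequentEdgeList([(1, 2), (2, 3), (4, 5)], [0.9, 0.8, 0.7])

    def test_increasing_appends_higher_indexed_edges_only(self):
        grown = ub.grow_patterns([ub.SubgraphPattern([(1, 2)])], self.M(), "increasing")
        # (1,2)+(2,3) is connected; (1,2)+(4,5) is dropped as disconnected
        assert grown == {ub.SubgraphPattern([(1, 2), (2, 3)])}

    def test_disconnected_candidates_dropped(self):
        grown = ub.grow_patterns([ub.SubgraphPattern([(2, 3)])], self.M(), "increasing")
        assert grown == set()

    def test_exhaustive_deduplicates_growth_routes(self):
        M = ub.FrequentEdgeList([(1, 2), (2, 3), (3, 4)], [0.9, 0.8, 0.7])
        grown = ub.grow_patterns(
            [
                ub.SubgraphPattern([(1, 2), (2, 3)]),
                ub.SubgraphPattern([(1, 2), (2, 3), (3, 4)]),  # no index above seed
            ],
            M,
            "exhaustive",
        )
        target = ub.SubgraphPattern([(1, 2), (2, 3), (3, 4)])
        assert list(grown).count(target) == 1

    def test_unknown_pattern_edge_rejected(self):
        with pytest.raises(ValueError, match="not a frequent edge"):
            ub.grow_patterns([ub.SubgraphPattern([(9, 10)])], self.M())


class TestMineUnfepg:
    def test_certain_triangle_yields_all_seven_connected_subgraphs(
        self, certain_triangle_cohort
    ):
        out = ub.mine_unfepg(certain_triangle_cohort, ub.MiningConfig(minsup=1.0))
        assert len(out) == 7  # 3 edges + 3 two-edge paths + 1 triangle
        assert all(f.esup == 1.0 for f in out)
        by_layer = sorted(f.layer for f in out)
        assert by_layer == [1, 1, 1, 2, 2, 2, 3]

    def test_no_frequent_edges_gives_empty_result(self, certain_triangle_cohort):
        net = ub.UncertainNetwork([1, 2], {(1, 2): 0.2})
        assert ub.mine_unfepg([net], ub.MiningConfig(minsup=0.5)) == []

    def test_patterns_reported_once_with_layer_equal_edge_count(self):
        nets = random_cohort(5)
        out = ub.mine_unfepg(nets, ub.MiningConfig(minsup=0.2, growth_mode="exhaustive"))
        patterns = [f.pattern for f in out]
        assert len(patterns) == len(set(patterns))
        assert all(f.layer == f.pattern.n_edges for f in out)

    def test_every_result_reverifies_independently(self):
        """Soundness: every mined pattern is connected and its reported esup
        matches a direct recomputation at >= minsup."""
        for seed in range(5):
            nets = random_cohort(seed)
            for mode in ("increasing", "exhaustive"):
                cfg = ub.MiningConfig(minsup=0.25, growth_mode=mode)
                for f in ub.mine_unfepg(nets, cfg):
                    direct = ub.expected_support(f.pattern, nets)
                    assert direct == pytest.approx(f.esup, abs=1e-9)
                    assert direct >= cfg.minsup

    def test_max_pattern_edges_caps_layer(self):
        nets = random_cohort(3)
        cfg = ub.MiningConfig(minsup=0.1, growth_mode="exhaustive", max_pattern_edges=2)
        assert all(f.layer <= 2 for f in ub.mine_unfepg(nets, cfg))


class TestOracleAgreement:
    def test_exhaustive_mode_matches_oracle(self):
        for seed in range(8):
            nets = random_cohort(seed)
            for minsup in (0.15, 0.35):
                cfg = ub.MiningConfig(minsup=minsup, growth_mode="exhaustive")
                mined = ub.mine_unfepg(nets, cfg)
                oracle = ub.mine_oracle(nets, cfg)
                assert [f.pattern for f in mined] == [f.pattern for f in oracle]
                np.testing.assert_allclose(
                    [f.esup for f in mined], [f.esup for f in oracle], atol=1e-9
                )

    def test_increasing_mode_loses_only_disconnected_prefixes(self):
        for seed in range(8):
            nets = random_cohort(seed)
            cfg = ub.MiningConfig(minsup=0.2)
            M = ub.frequent_edges(nets, cfg.minsup)
            inc = {f.pattern for f in ub.mine_unfepg(nets, cfg)}
            oracle = {f.pattern for f in ub.mine_oracle(nets, cfg)}
            assert inc <= oracle
            for missed in oracle - inc:
                assert not increasing_prefixes_connected(missed, M)
            for found in inc:
                assert increasing_prefixes_connected(found, M)

    def test_oracle_output_closed_under_subpatterns(self):
        """Anti-monotone closure: every connected sub-pattern of a reported
        pattern is reported."""
        nets = random_cohort(2)
        cfg = ub.MiningConfig(minsup=0.2)
        oracle = {f.pattern for f in ub.mine_oracle(nets, cfg)}
        for g in oracle:
            if g.n_edges < 2:
                continue
            for drop in range(g.n_edges):
                rest = [e for i, e in enumerate(g.edges) if i != drop]
                if ub.is_connected(rest):
                    assert ub.SubgraphPattern(rest) in oracle

    def test_oracle_guard_on_large_universe(self):
        nets = [ub.UncertainNetwork(range(9), {(0, 1): 0.9})]
        with pytest.raises(ValueError, match="8 nodes"):
            ub.mine_oracle(nets, ub.MiningConfig())


class TestCertainSpecialCase:
    def test_esup_equals_containment_fraction_on_binary_networks(self):
        rng = np.random.default_rng(5)
        nets = []
        for _ in range(8):
            probs = {}
            for i in range(5):
                for j in range(i + 1, 5):
                    if rng.random() < 0.6:
                        probs[(i, j)] = 1.0
            nets.append(ub.UncertainNetwork(range(5), probs))
        out = ub.mine_unfepg(nets, ub.MiningConfig(minsup=0.25, growth_mode="exhaustive"))
        assert out, "binary cohort should produce frequent patterns"
        for f in out:
            frac = np.mean(
                [all(e in net for e in f.pattern.edges) for net in nets]
            )
            assert f.esup == pytest.approx(frac)
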