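"""Detection heuristic: greedy breadth-first expansion and redundancy filter.

The independent oracle ``oracle_expand`` re-derives the expansion
post-condition naively (fresh mean computations, explicit layer sets) and
is checked against the implementation on random connected graphs.
"""

import itertools
import statistics

import numpy as np
import pytest

from htsnet.core import GeneScoreTable, Subnetwork
from htsnet.detection import detect_subnetworks, expand_seed, filter_redundant

from conftest import random_connected_network, random_score_table


def oracle_expand(net, scores, seed, th):
    """Naive layer simulation: keep any frontier node whose solo addition
    raises the mean by strictly more than th; add kept nodes together;
    rejected nodes never return."""
    members = {seed}
    rejected = set()
    while True:
        frontier = set()
        for m in members:
            frontier |= net.neighbors(m)
        frontier -= members | rejected
        if not frontier:
            break
        current = statistics.mean(scores[g] for g in members)
        kept = set()
        for v in frontier:
            trial = statistics.mean(scores[g] for g in members | {v})
            if trial - current > th:
                kept.add(v)
            else:
                rejected.add(v)
        if not kept:
            break
        members |= kept
    return members


class TestExpandSeed:
    def test_hand_traced_expansion(self, toy_net, toy_scores):
        """Seed A: layer 1 keeps B (+0.5) and closes C (-2.0, so E is never
        reached); layer 2 keeps D (+1/3); final {A,B,D} at 11/6."""
        sn = expand_seed(toy_net, toy_scores, "A", th=0.05)
        assert sn.members == {"A", "B", "D"}
        assert sn.score == pytest.approx(11 / 6)
        assert sn.seed == "A"

    def test_isolated_seed(self, toy_scores):
        import networkx as nx
        from htsnet.core import BioNetwork
        g = nx.Graph()
        g.add_node("A")
        net = BioNetwork(kind="interactome", graph=g)
        sn = expand_seed(net, toy_scores, "A", th=0.05)
        assert sn.members == {"A"}

    def test_improvement_of_exactly_th_is_rejected(self):
        import networkx as nx
        from htsnet.core import BioNetwork
        net = BioNetwork(kind="interactome", graph=nx.Graph([("A", "B")]))
        # Δ(B) = (z_B - z_A)/2 = 0.125 exactly (representable) -> rejected
        scores = GeneScoreTable(entries={"A": 1.0, "B": 1.25})
        sn = expand_seed(net, scores, "A", th=0.125)
        assert sn.members == {"A"}
        # just above the threshold -> kept
        scores = GeneScoreTable(entries={"A": 1.0, "B": 1.2500001})
        sn = expand_seed(net, scores, "A", th=0.125)
        assert sn.members == {"A", "B"}

    def test_unscored_seed_errors(self, toy_net):
        scores = GeneScoreTable(entries={"A": 1.0})
        with pytest.raises(KeyError):
            expand_seed(toy_net, scores, "B", th=0.05)

    @pytest.mark.parametrize("case", range(25))
    def test_matches_layer_simulation_oracle(self, case):
        """Implementation agrees with the naive oracle on random connected
        graphs of <= 7 nodes with random scores, from every seed."""
        rng = np.random.default_rng(5000 + case)
        n = int(rng.integers(2, 8))
        net = random_connected_network(n, 0.3, rng)
        scores = random_score_table(net, rng)
        th = float(rng.choice([0.0, 0.05, 0.2]))
        for seed in sorted(net.nodes):
            fast = expand_seed(net, scores, seed, th=th)
            assert fast.members == oracle_expand(net, scores, seed, th)

    def test_monotone_layer_growth(self):
        """Each layer's simultaneous addition raises the mean by more
        than th (implied by the per-node criterion)."""
        rng = np.random.default_rng(77)
        for _ in range(50):
            net = random_connected_network(int(rng.integers(4, 15)), 0.2, rng)
            scores = random_score_table(net, rng)
            for seed in sorted(net.nodes):
                sn = expand_seed(net, scores, seed, th=0.05)
                assert sn.score >= scores[seed] - 1e-12


class TestDetectSubnetworks:
    def test_toy_graph_enumeration(self, toy_net, toy_scores):
        """All 5 seeds expand; D and E stall at size 1 (their only
        neighbors lower the mean) and are dropped. Expected sets derived
        with the layer-simulation oracle."""
        subs = detect_subnetworks(toy_net, toy_scores, th=0.05)
        by_seed = {sn.seed: sn.members for sn in subs}
        assert by_seed == {
            "A": {"A", "B", "D"},
            "B": {"B", "D"},
            "C": {"A", "B", "C", "D", "E"},
        }
        assert all(sn.size >= 2 for sn in subs)

    def test_flat_field_yields_nothing(self, toy_net):
        scores = GeneScoreTable(entries={g: 1.0 for g in toy_net.nodes})
        assert detect_subnetworks(toy_net, scores, th=0.05) == []

    def test_two_node_graph_asymmetric_expansion(self):
        """Only the low-score seed grows (the high seed would lower its
        mean by recruiting the other); symmetric duplicates arise only for
        near-equal scores and then collapse in the redundancy filter."""
        import networkx as nx
        from htsnet.core import BioNetwork
        net = BioNetwork(kind="interactome", graph=nx.Graph([("A", "B")]))
        scores = GeneScoreTable(entries={"A": 0.0, "B": 10.0})
        subs = detect_subnetworks(net, scores, th=0.05)
        assert len(subs) == 1
        assert subs[0].seed == "A" and subs[0].members == {"A", "B"}

    def test_sorted_by_descending_score(self, rng):
        net = random_connected_network(20, 0.15, rng)
        scores = random_score_table(net, rng)
        subs = detect_subnetworks(net, scores, th=0.05)
        assert all(a.score >= b.score for a, b in zip(subs, subs[1:]))


def _sub(sid, members, score):
    return Subnetwork(id=sid, seed=sorted(members)[0], members=set(members),
                      network_kind="interactome", score=score)


class TestFilterRedundant:
    def test_both_overlaps_high_discards_lower_score(self):
        a = _sub("a", {"g1", "g2", "g3", "g4", "g5"}, 2.0)
        b = _sub("b", {"g1", "g2", "g3", "g4"}, 1.5)
        kept = filter_redundant([a, b], rate=0.8)
        assert [s.id for s in kept] == ["a"]

    def test_smaller_with_higher_score_is_kept(self):
        a = _sub("a", {f"g{i}" for i in range(1, 11)}, 1.0)
        b = _sub("b", {"g1", "g2", "g3", "g4", "g11"}, 2.0)
        kept = filter_redundant([a, b], rate=0.8)
        assert {s.id for s in kept} == {"a", "b"}

    def test_identical_duplicates_collapse(self):
        a = _sub("a", {"g1", "g2"}, 1.0)
        b = _sub("b", {"g1", "g2"}, 1.0)
        assert len(filter_redundant([a, b])) == 1

    def test_postcondition_no_mutually_redundant_pair(self, rng):
        for _ in range(30):
            pool = []
            universe = [f"g{i}" for i in range(20)]
            for i in range(12):
                size = int(rng.integers(2, 9))
                members = set(
                    universe[j] for j in rng.choice(20, size=size, replace=False))
                pool.append(_sub(f"s{i}", members, float(rng.normal())))
            kept = filter_redundant(pool, rate=0.8)
            for x, y in itertools.combinations(kept, 2):
                inter = len(x.members & y.members)
                assert not (inter / x.size >= 0.8 and inter / y.size >= 0.8)

    def test_order_independent_given_distinct_scores(self, rng):
        pool = []
        universe = [f"g{i}" for i in range(15)]
        for i in range(10):
            size = int(rng.integers(2, 7))
            members = set(
                universe[j] for j in rng.choice(15, size=size, replace=False))
            pool.append(_sub(f"s{i}", members, float(i) * 0.37))
        ref = {s.id for s in filter_redundant(pool)}
        for _ in range(5):
            perm = [pool[j] for j in rng.permutation(len(pool))]
            assert {s.id for s in filter_redundant(perm)} == ref
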