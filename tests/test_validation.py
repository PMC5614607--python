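import numpy as np
import pytest
from scipy.stats import kstest, norm

from htsnet.core import GeneScoreTable
from htsnet.validation import (EmpiricalNull, MixtureNull, ValidationConfig,
                               _random_set_means, _shuffled_scores,
                               fit_gaussian_mixture, mixture_tail_p,
                               null_type1, null_type3,
                               rewire_preserving_degrees,
                               validate_subnetworks)

from conftest import random_connected_network, random_score_table


class TestShuffle:
    def test_preserves_score_multiset(self, rng):
        table = GeneScoreTable(
            entries={f"g{i}": float(rng.normal()) for i in range(40)})
        shuffled = _shuffled_scores(table, rng)
        assert sorted(shuffled.entries.values()) == pytest.approx(
            sorted(table.entries.values()))
        assert set(shuffled.entries) == set(table.entries)


class TestRewiring:
    def test_degree_sequence_conserved(self, rng):
        for _ in range(20):
            net = random_connected_network(int(rng.integers(5, 25)), 0.2, rng)
            before = sorted(d for _, d in net.graph.degree())
            rewired = rewire_preserving_degrees(net, rng=rng)
            after = sorted(d for _, d in rewired.graph.degree())
            assert before == after
            assert rewired.nodes == net.nodes

    def test_star_cannot_be_swapped(self, rng):
        import networkx as nx
        from htsnet.core import BioNetwork
        star = BioNetwork(kind="interactome",
                          graph=nx.star_graph(4))
        with pytest.warns(UserWarning, match="constrained"):
            out = rewire_preserving_degrees(star, n_swaps=10, rng=rng,
                                            max_tries_factor=20)
        assert set(out.graph.edges) == set(star.graph.edges)

    def test_edge_set_changes_on_random_graph(self, rng):
        net = random_connected_network(20, 0.25, rng)
        rewired = rewire_preserving_degrees(net, rng=rng)
        canon = lambda g: {tuple(sorted(e)) for e in g.edges()}
        assert canon(rewired.graph) != canon(net.graph)


class TestMixtureFit:
    def test_single_normal_recovery(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, size=5000)
        mix = fit_gaussian_mixture(x, max_components=3, rng=rng)
        mean = float(np.sum(mix.weights * mix.means))
        assert abs(mean) < 0.1
        sd = float(np.sqrt(np.sum(mix.weights * (mix.sds**2 + mix.means**2))
                           - mean**2))
        assert abs(sd - 1.0) < 0.1

    def test_bimodal_recovery(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 1, 2500), rng.normal(6, 1, 2500)])
        mix = fit_gaussian_mixture(x, max_components=3, rng=rng)
        assert mix.n_components >= 2
        got = sorted(mix.means)
        assert abs(got[0] - 0.0) < 0.2
        assert abs(got[-1] - 6.0) < 0.2

    def test_small_sample_fallback(self):
        rng = np.random.default_rng(5)
        mix = fit_gaussian_mixture([1.0, 2.0, 3.0, 2.0, 1.5], rng=rng)
        assert mix.n_components == 1
        assert mix.means[0] == pytest.approx(1.9)

    def test_zero_variance_floored(self):
        rng = np.random.default_rng(6)
        with pytest.warns(UserWarning, match="zero-variance"):
            mix = fit_gaussian_mixture([2.0] * 20, rng=rng)
        assert mix.sds[0] > 0
        assert mixture_tail_p(mix, 3.0) < 1e-6


class TestTailP:
    def test_standard_normal_tail(self):
        mix = MixtureNull("type1", "pooled", [0.0] * 10,
                          [1.0], [0.0], [1.0])
        assert mixture_tail_p(mix, 1.6449) == pytest.approx(0.05, abs=1e-3)

    def test_two_component_closed_form(self):
        mix = MixtureNull("type1", "pooled", [0.0] * 10,
                          [0.5, 0.5], [0.0, 2.0], [1.0, 1.0])
        expected = 0.5 * norm.sf(2.0) + 0.5 * 0.5
        assert mixture_tail_p(mix, 2.0) == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(0.26138, abs=1e-4)

    def test_limits_and_monotonicity(self):
        mix = MixtureNull("type1", "pooled", [0.0] * 10,
                          [0.3, 0.7], [0.0, 1.0], [1.0, 0.5])
        assert mixture_tail_p(mix, -50.0) == pytest.approx(1.0)
        xs = np.linspace(-5, 5, 60)
        ps = [mixture_tail_p(mix, x) for x in xs]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_self_calibration_uniform(self):
        """Tail p-values of draws from the fitted mixture itself are
        uniform — the calibration property of a correct tail evaluator."""
        rng = np.random.default_rng(11)
        mix = MixtureNull("type1", "pooled", [0.0] * 10,
                          [0.6, 0.4], [0.0, 3.0], [1.0, 0.7])
        comp = rng.choice(2, p=mix.weights, size=2000)
        draws = rng.normal(mix.means[comp], mix.sds[comp])
        ps = [mixture_tail_p(mix, x) for x in draws]
        stat = kstest(ps, "uniform").statistic
        assert stat < 0.05


class TestNullType3:
    def test_singleton_means_equal_score_distribution(self, rng):
        table = GeneScoreTable(
            entries={f"g{i}": float(i) for i in range(20)})
        means = _random_set_means(table, size=1, m=4000, rng=rng)
        assert set(np.unique(means)) <= set(float(i) for i in range(20))

    def test_full_set_degenerate(self, rng):
        table = GeneScoreTable(entries={"a": 1.0, "b": 2.0, "c": 3.0})
        means = _random_set_means(table, size=3, m=50, rng=rng)
        assert np.allclose(means, 2.0)

    def test_pair_means_enumeration(self, rng):
        """Scores {0,0,3,3}: C(4,2)=6 pairs give means 0 (1/6), 1.5 (4/6),
        3 (1/6)."""
        table = GeneScoreTable(
            entries={"a": 0.0, "b": 0.0, "c": 3.0, "d": 3.0})
        means = _random_set_means(table, size=2, m=30000, rng=rng)
        freqs = {v: np.mean(means == v) for v in (0.0, 1.5, 3.0)}
        assert sum(freqs.values()) == pytest.approx(1.0)
        assert freqs[0.0] == pytest.approx(1 / 6, abs=0.02)
        assert freqs[1.5] == pytest.approx(4 / 6, abs=0.02)
        assert freqs[3.0] == pytest.approx(1 / 6, abs=0.02)

    def test_size_exceeding_universe_errors(self, rng):
        table = GeneScoreTable(entries={"a": 1.0})
        cfg = ValidationConfig(m_samples=10)
        with pytest.raises(ValueError):
            null_type3(table, [5], cfg, rng)


class TestValidateSubnetworks:
    def _nulls(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(0, 1, 500)
        n1 = EmpiricalNull("type1", np.full(500, 3), samples, fit_seed=1)
        n2 = EmpiricalNull("type2", np.full(500, 3), samples, fit_seed=2)
        n3 = {3: fit_gaussian_mixture(samples, 2, np.random.default_rng(3),
                                      "type3", 3)}
        return n1, n2, n3

    def _sub(self, score):
        from htsnet.core import Subnetwork
        return Subnetwork(id="s", seed="a", members={"a", "b", "c"},
                          network_kind="interactome", score=score)

    def test_bonferroni_multiplication_and_conjunction(self):
        n1, n2, n3 = self._nulls()
        cfg = ValidationConfig(alpha_int=0.05, bonferroni=True)
        subs = [self._sub(5.0)] + [self._sub(0.0) for _ in range(9)]
        out = validate_subnetworks(subs, n1, n2, n3, cfg)
        assert out[0].retained
        # raw p multiplied by family size 10
        raw = n1.tail_p(5.0, 3)
        assert out[0].p1 == pytest.approx(min(1.0, raw * 10))
        assert not out[1].retained  # p ~ 0.5 for score 0

    def test_cap_at_one(self):
        n1, n2, n3 = self._nulls()
        cfg = ValidationConfig(bonferroni=True)
        subs = [self._sub(0.2) for _ in range(10)]
        out = validate_subnetworks(subs, n1, n2, n3, cfg)
        assert all(sn.p1 == 1.0 for sn in out)

    def test_any_failed_p_rejects(self):
        n1, n2, _ = self._nulls()
        # type3 null centered far above every score -> p3 ~ 1
        n3 = {3: MixtureNull("type3", 3, [0.0] * 10, [1.0], [50.0], [1.0])}
        cfg = ValidationConfig(alpha_int=0.05)
        out = validate_subnetworks([self._sub(6.0)], n1, n2, n3, cfg)
        assert not out[0].retained


class TestSizeBinning:
    def test_size_matched_bins_widen_until_filled(self):
        sizes = np.array([2] * 60 + [3] * 5 + [10] * 60)
        scores = np.concatenate([np.zeros(60), np.ones(5), np.full(60, 5.0)])
        null = EmpiricalNull("type1", sizes, scores, min_bin=50, fit_seed=0)
        assert len(null._bin_samples(2)) == 60
        # size 3 bin is sparse -> widens to include size-2 samples
        b3 = null._bin_samples(3)
        assert len(b3) >= 50 and 0.0 in b3
        # pooled mode ignores size
        pooled = EmpiricalNull("type1", sizes, scores, size_matched=False,
                               fit_seed=0)
        assert len(pooled._bin_samples(3)) == 125

    def test_reproducible_given_seed(self, rng):
        net = random_connected_network(25, 0.15, rng)
        table = random_score_table(net, rng)
        cfg = ValidationConfig(n_reps=3, m_samples=200)
        a = null_type1(net, table, cfg, np.random.default_rng(9))
        b = null_type1(net, table, cfg, np.random.default_rng(9))
        assert np.array_equal(a.scores, b.scores)
        assert np.array_equal(a.sizes, b.sizes)
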