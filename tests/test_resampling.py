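import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from dbsrecruit import resampling as rs


class TestBootstrapP:
    @pytest.mark.parametrize(
        "x,n,expected",
        [(0, 1000, 1 / 1001), (1000, 1000, 1.0), (49, 999, 0.05)],
    )
    def test_hand_values(self, x, n, expected):
        assert rs.bootstrap_p(x, n) == pytest.approx(expected, rel=1e-12)

    def test_x_out_of_range_errors(self):
        with pytest.raises(ValueError):
            rs.bootstrap_p(1001, 1000)
        with pytest.raises(ValueError):
            rs.bootstrap_p(-1, 1000)

    @given(n=st.integers(1, 5000), x=st.integers(0, 5000))
    @settings(max_examples=50, derandomize=True)
    def test_in_unit_interval_and_monotone(self, n, x):
        x = min(x, n)
        p = rs.bootstrap_p(x, n)
        assert 0 < p <= 1
        if x < n:
            assert rs.bootstrap_p(x + 1, n) > p


class TestGlassDelta:
    def test_hand_values(self):
        assert rs.glass_delta(2.0, 1.0, 0.5) == pytest.approx(2.0)
        assert rs.glass_delta(3.3, 3.3, 1.7) == 0.0

    def test_matches_null_sample_moments(self, rng):
        null = rng.normal(5.0, 2.0, size=4000)
        obs = 9.0
        res = rs.summarize_bootstrap(obs, null)
        expected = (obs - null.mean()) / null.std(ddof=1)
        assert res.effect_size == pytest.approx(expected)

    def test_zero_sd_errors(self):
        with pytest.raises(ValueError):
            rs.glass_delta(1.0, 0.0, 0.0)


class TestHolmBonferroni:
    def test_worked_example(self):
        # 0.01 rejected at 0.05/3; then 0.03 vs 0.025 fails and testing stops
        reject = rs.holm_bonferroni([0.01, 0.04, 0.03], alpha=0.05)
        assert reject.tolist() == [True, False, False]

    def test_all_ones_no_rejections(self):
        assert not rs.holm_bonferroni([1.0, 1.0, 1.0]).any()

    def test_agrees_with_statsmodels_on_random_vectors(self, rng):
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 12))
            ours = rs.holm_bonferroni(p, alpha=0.05)
            ref = multipletests(p, alpha=0.05, method="holm")[0]
            np.testing.assert_array_equal(ours, ref)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            rs.holm_bonferroni([0.2, 1.4])


class TestPopulationOverlap:
    def test_observed_conditional_probability(self):
        res = rs.population_overlap({1, 2, 3, 4}, {3, 4, 5}, range(10), n_boot=50, seed=0)
        assert res.observed == pytest.approx(0.5)

    def test_identical_sets_give_one(self):
        res = rs.population_overlap({1, 2}, {1, 2}, range(10), n_boot=50, seed=0)
        assert res.observed == pytest.approx(1.0)

    def test_null_mean_matches_hypergeometric_expectation(self):
        # E[|A n B|]/|A| = |B|/|U| when both sets are uniform draws
        universe = range(200)
        res = rs.population_overlap(
            set(range(20)), set(range(20, 40)), universe, n_boot=2000, seed=1
        )
        null_mean = float(np.mean(res.null_samples))
        assert null_mean == pytest.approx(20 / 200, abs=0.01)

    def test_empty_set_a_errors(self):
        with pytest.raises(ValueError):
            rs.population_overlap(set(), {1}, range(5))

    def test_reproducible_under_seed(self):
        a = rs.population_overlap({1, 2, 3}, {2, 3, 4}, range(30), n_boot=200, seed=7)
        b = rs.population_overlap({1, 2, 3}, {2, 3, 4}, range(30), n_boot=200, seed=7)
        np.testing.assert_array_equal(a.null_samples, b.null_samples)
        assert a.p == b.p


def brute_force_consistency(labels_by_block, cluster):
    """Independent oracle: per-neuron membership scan."""
    denominator, numerator = set(), set()
    for labels in labels_by_block.values():
        for neuron, lab in labels.items():
            if lab == cluster:
                denominator.add(neuron)
    for neuron in denominator:
        other = False
        for labels in labels_by_block.values():
            lab = labels.get(neuron)
            if lab is not None and lab != cluster:
                other = True
        if not other:
            numerator.add(neuron)
    if not denominator:
        return float("nan")
    return len(numerator) / len(denominator)


class TestConsistency:
    def test_worked_set_example(self):
        # TE sets {a,b,c}/{a,b,d}/{a,e}; c is also SE in block 2
        te, se = ("transient", "excited"), ("sustained", "excited")
        labels = {
            0: {0: te, 1: te, 2: te},
            1: {0: te, 1: te, 3: te, 2: se},
            2: {0: te, 4: te},
        }
        stat = rs.consistency_statistic(labels)
        assert stat[te] == pytest.approx(4 / 5)

    def test_identical_blocks_fully_consistent(self):
        te = ("transient", "excited")
        si = ("sustained", "inhibited")
        labels = {b: {0: te, 1: te, 2: si} for b in range(3)}
        stat = rs.consistency_statistic(labels)
        assert stat[te] == 1.0
        assert stat[si] == 1.0
        assert np.isnan(stat[("transient", "inhibited")])

    def test_matches_brute_force_oracle_on_random_configs(self, rng):
        clusters = list(rs.CLUSTERS)
        for _ in range(300):
            n_neurons = int(rng.integers(1, 7))
            labels = {}
            for b in range(3):
                block = {}
                for neuron in range(n_neurons):
                    draw = rng.integers(0, len(clusters) + 1)
                    if draw < len(clusters):
                        block[neuron] = clusters[draw]
                labels[b] = block
            stat = rs.consistency_statistic(labels)
            for c in clusters:
                expected = brute_force_consistency(labels, c)
                if np.isnan(expected):
                    assert np.isnan(stat[c])
                else:
                    assert stat[c] == pytest.approx(expected)

    def test_null_calibration_p_uniform(self, rng):
        # labels drawn from the null itself: p should be non-extreme and
        # Glass's Delta near zero on average
        universe = np.arange(40)
        ps, deltas = [], []
        for rep in range(20):
            labels = {}
            for b in range(2):
                drawn = rng.choice(universe, size=8, replace=False)
                labels[b] = {int(n): ("transient", "excited") for n in drawn[:5]}
                labels[b].update({int(n): ("sustained", "excited") for n in drawn[5:]})
            out = rs.consistency_of_modulation(labels, universe, n_boot=200, seed=rep)
            r = out[("transient", "excited")]["result"]
            if r is not None:
                ps.append(r.p)
                deltas.append(r.effect_size)
        assert np.mean(ps) > 0.2  # not systematically significant
        assert abs(np.mean(deltas)) < 0.6

    def test_requires_two_blocks(self):
        with pytest.raises(ValueError):
            rs.consistency_of_modulation({0: {}}, np.arange(5))
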