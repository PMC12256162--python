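from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lgdnovelty import clusterstats as cs


class TestPointwiseT:
    def test_hand_computed_pooled_t(self):
        """{1,2,3} vs {4,5,6}: pooled t = -3/sqrt(1*(1/3+1/3)) = -3.674, df = 4."""
        t, df = cs.pointwise_t(np.array([[1.0], [2.0], [3.0]]), np.array([[4.0], [5.0], [6.0]]))
        assert df == 4
        assert t[0] == pytest.approx(-3.674, abs=1e-3)

    def test_identical_groups_give_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 10))
        t, _ = cs.pointwise_t(x, x)
        assert np.allclose(t, 0.0)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_antisymmetric_under_group_swap(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(4, 6)), rng.normal(size=(7, 6))
        t_ab, df_ab = cs.pointwise_t(a, b)
        t_ba, df_ba = cs.pointwise_t(b, a)
        assert df_ab == df_ba == 9
        assert np.allclose(t_ab, -t_ba)

    def test_degenerate_variance_yields_zero_with_warning(self):
        a = np.ones((3, 2))
        b = np.ones((3, 2))
        b[:, 1] = [1.0, 2.0, 3.0]
        with pytest.warns(RuntimeWarning, match="degenerate"):
            t, _ = cs.pointwise_t(a, b)
        assert t[0] == 0.0 and t[1] != 0.0

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="two trials"):
            cs.pointwise_t(np.ones((1, 3)), np.ones((5, 3)))


class TestTThreshold:
    def test_normal_limit_quantile(self):
        assert cs.t_threshold(10**7, "two-tailed", 99.5) == pytest.approx(2.576, abs=1e-3)

    def test_tabulated_quantile_df100(self):
        # printed t-table value: 99th percentile (one-tailed 0.01), df = 100
        assert cs.t_threshold(100, "one-tailed", 99.0) == pytest.approx(2.364, abs=1e-3)

    def test_median_is_zero_and_df_validation(self):
        assert cs.t_threshold(5, "one-tailed", 50.0) == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            cs.t_threshold(0, "one-tailed", 99.0)


class TestFindClusters:
    def test_two_tailed_sign_split(self):
        cl = cs.find_clusters(np.array([0, 3, 4, 0, -3, -4.0]), 2.5, "two-tailed")
        assert [(c.start_idx, c.end_idx, c.sum_t) for c in cl] == [(1, 3, 7.0), (4, 6, -7.0)]

    def test_no_clusters_in_flat_series(self):
        assert cs.find_clusters(np.zeros(10), 2.5, "one-tailed") == []

    def test_one_tailed_run(self):
        cl = cs.find_clusters(np.array([3.0, 3.0]), 2.5, "one-tailed")
        assert len(cl) == 1 and cl[0].sum_t == 6.0

    def test_adjacent_opposite_signs_split(self):
        cl = cs.find_clusters(np.array([3.0, -3.0, 3.0]), 2.5, "two-tailed")
        assert [c.sum_t for c in cl] == [3.0, -3.0, 3.0]

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 500))
    def test_matches_naive_scan(self, seed):
        """Cluster boundaries and sums agree with a sample-by-sample reference scan."""
        rng = np.random.default_rng(seed)
        t = rng.normal(scale=2.0, size=40)
        thr = 1.5
        got = [(c.start_idx, c.end_idx, c.sum_t) for c in cs.find_clusters(t, thr, "two-tailed")]
        expected = []
        i = 0
        while i < t.size:
            s = np.sign(t[i]) if abs(t[i]) > thr else 0
            if s == 0:
                i += 1
                continue
            j = i
            while j < t.size and abs(t[j]) > thr and np.sign(t[j]) == s:
                j += 1
            expected.append((i, j, float(t[i:j].sum())))
            i = j
        assert got == pytest.approx(expected)


class TestMonteCarloP:
    def test_add_one_formula(self):
        null = np.arange(1.0, 10_001.0)
        assert cs.monte_carlo_p(10_001.0, null) == pytest.approx(1 / 10_001)
        assert cs.monte_carlo_p(0.5, null) == 1.0
        assert cs.monte_carlo_p(5000.0, null) == pytest.approx(0.5, abs=1e-3)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            cs.monte_carlo_p(1.0, np.array([]))


class TestPermutationNull:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        std, dev = rng.normal(size=(8, 30)), rng.normal(size=(8, 30))
        cfg = cs.ClusterTestConfig(n_permutations=200, seed=3)
        a = cs.permutation_null(std, dev, cfg)
        b = cs.permutation_null(std, dev, cfg)
        assert np.array_equal(a, b)

    def test_single_permutation(self):
        rng = np.random.default_rng(1)
        null = cs.permutation_null(
            rng.normal(size=(5, 20)), rng.normal(size=(5, 20)),
            cs.ClusterTestConfig(n_permutations=1, seed=0),
        )
        assert null.shape == (1,)

    def test_monte_carlo_converges_to_exhaustive_enumeration(self):
        """3-vs-3 toy: MC p matches the exact p over all 20 partitions."""
        rng = np.random.default_rng(3)
        std = rng.normal(size=(3, 4))
        dev = rng.normal(size=(3, 4)) + 1.0
        n_perm = 4000
        cfg = cs.ClusterTestConfig(n_permutations=n_perm, seed=5, percentile=95.0)
        res = cs.ClusterPermutationTest(std, dev, config=cfg).fit()
        assert res.clusters, "toy effect should produce at least one cluster"

        x = np.vstack([std, dev])
        thr = cs.t_threshold(4, "two-tailed", 95.0)
        null = []
        for comb in combinations(range(6), 3):
            dsel = np.zeros(6, bool)
            dsel[list(comb)] = True
            tt, _ = cs.pointwise_t(x[~dsel], x[dsel])
            cls = cs.find_clusters(tt, thr, "two-tailed")
            null.append(max((abs(c.sum_t) for c in cls), default=0.0))
        null = np.array(null)
        for c in res.clusters:
            p_exact = float((null >= abs(c.sum_t)).mean())
            se = np.sqrt(max(p_exact * (1 - p_exact), 1e-4) / n_perm)
            assert abs(c.p_mc - p_exact) <= 3 * se + 2 / n_perm

    def test_two_tailed_p_invariant_under_relabeling(self):
        """Swapping which group is 'standard' leaves two-tailed p-values unchanged
        up to Monte-Carlo error (the random partitions are redrawn)."""
        rng = np.random.default_rng(7)
        std = rng.normal(size=(10, 50))
        dev = rng.normal(size=(10, 50)) + 0.6
        cfg = cs.ClusterTestConfig(n_permutations=2000, seed=2)
        res_a = cs.ClusterPermutationTest(std, dev, config=cfg).fit()
        res_b = cs.ClusterPermutationTest(dev, std, config=cfg).fit()
        assert [abs(c.sum_t) for c in res_a.clusters] == pytest.approx(
            [abs(c.sum_t) for c in res_b.clusters]
        )
        pa = sorted(c.p_mc for c in res_a.clusters)
        pb = sorted(c.p_mc for c in res_b.clusters)
        assert pa == pytest.approx(pb, abs=0.05)


class TestFDR:
    def test_step_up_example(self):
        """Direct BH computation: adjusted p = min_k>=rank (m/k) p_(k), monotone."""
        p_adj, reject = cs.fdr_adjust([0.001, 0.02, 0.04, 0.6], q=0.05)
        assert p_adj == pytest.approx([0.004, 0.04, 0.04 * 4 / 3, 0.6])
        assert list(reject) == [True, True, False, False]

    def test_all_ones_and_singleton(self):
        p_adj, reject = cs.fdr_adjust([1.0, 1.0, 1.0])
        assert not reject.any() and np.allclose(p_adj, 1.0)
        p_adj, reject = cs.fdr_adjust([0.04])
        assert reject[0] and p_adj[0] == pytest.approx(0.04)

    def test_empty_input(self):
        p_adj, reject = cs.fdr_adjust([])
        assert p_adj.size == 0 and reject.size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            cs.fdr_adjust([0.0, 0.5])


class TestModelObject:
    def test_summary_table_columns(self):
        rng = np.random.default_rng(0)
        std = rng.normal(size=(12, 60))
        dev = rng.normal(size=(12, 60))
        dev[:, 20:35] += 1.5
        res = cs.ClusterPermutationTest(
            std, dev, config=cs.ClusterTestConfig(n_permutations=300, seed=1)
        ).fit()
        tbl = res.summary()
        assert list(tbl.columns) == ["start_ms", "end_ms", "sum_t", "p_mc", "p_adj"]
        assert res.significant(0.05, adjusted=False)

    def test_one_tailed_detects_increases_only(self):
        """The high-gamma test flags deviant power increases, not decreases."""
        rng = np.random.default_rng(4)
        std = rng.normal(size=(40, 80))
        up = rng.normal(size=(40, 80))
        up[:, 30:50] += 1.0
        down = rng.normal(size=(40, 80))
        down[:, 30:50] -= 1.0
        cfg = cs.ClusterTestConfig(tail="one-tailed", percentile=99.0,
                                   n_permutations=400, seed=0)
        assert cs.ClusterPermutationTest(std, up, config=cfg).fit().significant(0.05)
        assert not cs.ClusterPermutationTest(std, down, config=cfg).fit().significant(0.05)

    def test_agrees_with_mne_cluster_test(self):
        """Independent cross-check against mne's cluster permutation test."""
        from mne.stats import permutation_cluster_test

        rng = np.random.default_rng(9)
        std = rng.normal(size=(20, 60))
        dev = rng.normal(size=(20, 60))
        dev[:, 25:40] += 1.2
        cfg = cs.ClusterTestConfig(n_permutations=1000, seed=0, percentile=99.5)
        ours = cs.ClusterPermutationTest(std, dev, config=cfg).fit()
        f_thr = cs.t_threshold(38, "two-tailed", 99.5) ** 2
        _, _, pvals, _ = permutation_cluster_test(
            [std, dev], threshold=f_thr, n_permutations=1000, seed=0, tail=1,
            out_type="mask", verbose=False,
        )
        assert ours.min_p < 0.01 and pvals.min() < 0.01

        null_dev = rng.normal(size=(20, 60))
        ours_null = cs.ClusterPermutationTest(std, null_dev, config=cfg).fit()
        _, _, pvals_null, _ = permutation_cluster_test(
            [std, null_dev], threshold=f_thr, n_permutations=1000, seed=0, tail=1,
            out_type="mask", verbose=False,
        )
        assert ours_null.min_p > 0.05
        assert pvals_null.size == 0 or pvals_null.min() > 0.05


def test_power_monotone_in_amplitude():
    """Flagged fraction does not decrease as the planted amplitude grows."""
    from lgdnovelty.validation import run_power_curve

    rates = run_power_curve((0.0, 0.4, 0.8), seed=1, n_sites=30, n_permutations=400)
    assert rates[0] <= rates[1] + 0.1  # near-null level with binomial slack
    assert rates[1] <= rates[2] + 0.05
    assert rates[2] > rates[0]
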