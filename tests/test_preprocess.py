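import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bmdkit.data_io import ExpressionDataset
from bmdkit.preprocess import (FilterSettings, anova_pvalue, bh_adjust,
                               compute_fold_change, filter_probes,
                               isotonic_group_means, pooled_within_sd,
                               resampling_pvalue, screen_probes, trend_fit,
                               williams_statistic)


# -- independent oracles -----------------------------------------------------

def maxmin_oracle(means, sizes, direction="increasing"):
    """Brute-force max-min enumeration of the isotonic MLE."""
    means = np.asarray(means, float)
    sizes = np.asarray(sizes, float)
    K = means.size
    sign = 1.0 if direction == "increasing" else -1.0
    m = sign * means
    out = np.empty(K)
    for i in range(K):
        best = -np.inf
        for u in range(i + 1):
            worst = np.inf
            for v in range(u, K):
                w = sizes[u:v + 1]
                worst = min(worst, float(np.dot(w, m[u:v + 1]) / w.sum()))
            best = max(best, worst)
        out[i] = sign * best
    return out


def bh_oracle(p):
    """Step-up recursion: q_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, min(1.0, m * p[order[rank - 1]] / rank))
        q[order[rank - 1]] = running
    return q


class TestFoldChange:
    def test_no_change_gives_unity(self):
        assert compute_fold_change([5.0, 5.0], 5.0, 2) == 1.0

    def test_absmax_picks_largest_magnitude_with_sign(self):
        # log2 diffs (+1, -2) -> candidates (2, -4) -> f = -4
        assert compute_fold_change([1.0, -2.0], 0.0, 2) == pytest.approx(-4.0)

    def test_base10_diff_of_log10_2_gives_twofold(self):
        assert compute_fold_change([0.30103], 0.0, 10) == pytest.approx(2.0, abs=1e-6)

    def test_magnitude_always_at_least_one(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            f = compute_fold_change(rng.normal(size=4), rng.normal(), 2)
            assert abs(f) >= 1.0

    def test_requires_a_non_control_level(self):
        with pytest.raises(ValueError):
            compute_fold_change([], 5.0, 2)


class TestAnova:
    def test_two_groups_equals_pooled_t_test(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=5), rng.normal(1, 1, size=6)
        ds = ExpressionDataset(["p"], np.concatenate([a, b])[None, :],
                               [0] * 5 + [1] * 6, 2,
                               [f"s{i}" for i in range(11)])
        p_t = stats.ttest_ind(a, b).pvalue
        assert anova_pvalue(ds, "p") == pytest.approx(p_t, abs=1e-12)

    def test_identical_group_means_give_p_one(self):
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        ds = ExpressionDataset(["p"], y[None, :], [0, 0, 1, 1, 2, 2], 2,
                               [f"s{i}" for i in range(6)])
        assert anova_pvalue(ds, "p") == pytest.approx(1.0)

    def test_matches_f_distribution_oracle(self):
        # fixed 3 groups x 4 samples: compute F and its tail by hand
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, 4) for m in (0.0, 0.5, 1.5)]
        y = np.concatenate(groups)
        ds = ExpressionDataset(["p"], y[None, :], np.repeat([0, 1, 2], 4), 2,
                               [f"s{i}" for i in range(12)])
        gm = [g.mean() for g in groups]
        grand = y.mean()
        ssb = sum(4 * (m - grand) ** 2 for m in gm)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        F = (ssb / 2) / (ssw / 9)
        p_oracle = stats.f.sf(F, 2, 9)
        assert anova_pvalue(ds, "p") == pytest.approx(p_oracle, abs=1e-10)


class TestIsotonicMeans:
    def test_monotone_input_is_fixed_point(self):
        np.testing.assert_allclose(
            isotonic_group_means([1, 2, 3], [1, 1, 1]), [1, 2, 3])

    def test_violating_pair_pools_unweighted(self):
        np.testing.assert_allclose(isotonic_group_means([3, 1], [1, 1]), [2, 2])

    def test_violating_pair_pools_weighted(self):
        np.testing.assert_allclose(isotonic_group_means([3, 1], [1, 3]),
                                   [1.5, 1.5])

    @pytest.mark.parametrize("direction", ["increasing", "decreasing"])
    def test_matches_exhaustive_enumeration(self, direction):
        rng = np.random.default_rng(4)
        for _ in range(300):
            K = rng.integers(2, 7)
            means = rng.normal(size=K)
            sizes = rng.integers(1, 6, size=K)
            got = isotonic_group_means(means, sizes, direction)
            want = maxmin_oracle(means, sizes, direction)
            np.testing.assert_allclose(got, want, atol=1e-12)
            diffs = np.diff(got)
            assert np.all(diffs >= -1e-12) if direction == "increasing" \
                else np.all(diffs <= 1e-12)

    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=6),
           st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_output_monotone_property(self, means, data):
        sizes = data.draw(st.lists(st.integers(1, 5), min_size=len(means),
                                   max_size=len(means)))
        mu = isotonic_group_means(means, sizes, "increasing")
        assert np.all(np.diff(mu) >= -1e-9)


class TestWilliamsStatistic:
    def test_zero_when_isotonic_means_equal_control(self):
        assert williams_statistic(np.array([0.0, 0.0, 0.0]), 0.0, 1.0,
                                  [4, 4, 4]) == 0.0

    def test_hand_computed_example(self):
        t = williams_statistic(np.array([0.0, 1.0, 2.0]), 0.0, 1.0, [4, 4, 4])
        assert t == pytest.approx(2.0 / np.sqrt(0.5), abs=1e-12)

    def test_negation_symmetry(self, toy_dataset):
        fit = trend_fit(toy_dataset, "pU")
        neg = ExpressionDataset(toy_dataset.probe_ids, -toy_dataset.values,
                                toy_dataset.doses, 2, toy_dataset.sample_ids)
        fit_neg = trend_fit(neg, "pU")
        assert fit.statistic == pytest.approx(fit_neg.statistic, rel=1e-12)
        assert fit.direction != fit_neg.direction

    def test_zero_within_variance_rejected(self):
        ds = ExpressionDataset(["p"], [[1.0, 1.0, 2.0, 2.0]], [0, 0, 1, 1], 2,
                               list("abcd"))
        with pytest.raises(ValueError, match="variance"):
            trend_fit(ds, "p")


class TestResamplingPvalue:
    def test_flat_group_means_give_p_one(self):
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        ds = ExpressionDataset(["p"], y[None, :], [0, 0, 0, 0, 1, 1, 1, 1], 2,
                               [f"s{i}" for i in range(8)])
        # observed T = 0, and T_b >= 0 always
        assert resampling_pvalue(ds, "p", "permutation", 200, 1) == 1.0

    def test_lower_bound_one_over_b_plus_one(self, five_level_dataset):
        p = resampling_pvalue(five_level_dataset, "p00", "permutation", 100, 0)
        assert p >= 1 / 101
        # strong trend, should sit at the lower bound
        assert p == pytest.approx(1 / 101)

    def test_matches_exhaustive_enumeration_two_by_two(self):
        y = np.array([0.1, 0.9, 1.4, 2.2])
        doses = np.array([0, 0, 1, 1.0])
        ds = ExpressionDataset(["p"], y[None, :], doses, 2, list("abcd"))
        idx = [np.array([0, 1]), np.array([2, 3])]
        sizes = np.array([2, 2])

        def stat(vals):
            means = np.array([vals[:2].mean(), vals[2:].mean()])
            s = pooled_within_sd(vals, idx)
            ts = []
            for d in ("increasing", "decreasing"):
                mu = isotonic_group_means(means, sizes, d)
                ts.append(williams_statistic(mu, means[0], s, sizes))
            return max(ts)

        t_obs = stat(y)
        exhaustive = [stat(y[list(perm)])
                      for perm in itertools.permutations(range(4))]
        p_exact = np.mean([t >= t_obs - 1e-12 for t in exhaustive])
        # with B large the permutation estimate converges to the exhaustive value
        p_hat = resampling_pvalue(ds, "p", "permutation", 4000, 123)
        assert p_hat == pytest.approx(p_exact, abs=0.03)

    def test_bootstrap_null_gives_large_p_for_flat_probe(self, toy_dataset):
        p = resampling_pvalue(toy_dataset, "pF", "bootstrap", 300, 5)
        assert p > 0.05

    def test_requires_minimum_replicates(self, toy_dataset):
        with pytest.raises(ValueError, match="at least 100"):
            resampling_pvalue(toy_dataset, "pU", "permutation", 50, 0)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]).tolist() == [0.2]

    def test_step_up_recursion_by_hand(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_matches_independent_step_up_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_order_preserving(self):
        rng = np.random.default_rng(7)
        p = rng.random(50)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestFilterProbes:
    @pytest.fixture()
    def results(self, five_level_dataset):
        return screen_probes(five_level_dataset,
                             FilterSettings(2.0, 0.05, "anova", seed=3),
                             tests={"anova"})

    def test_strong_probes_pass_null_probes_fail(self, results):
        passed = set(results.loc[results.passed, "probe_id"])
        assert passed == {f"p{i:02d}" for i in range(10)}

    def test_fold_change_boundary_inclusive_p_boundary_strict(self):
        import pandas as pd
        df = pd.DataFrame({
            "probe_id": ["small_fc", "exact_fc", "exact_p"],
            "fold_change": [1.5, 2.0, 4.0],
            "p_anova": [0.001, 0.001, 0.05],
            "valid": [True, True, True]})
        settings = FilterSettings(2.0, 0.05, "anova")
        assert filter_probes(df, settings) == ["exact_fc"]

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError, match="unknown test"):
            FilterSettings(which_test="bogus")

    def test_screen_invariant_to_sample_order(self, five_level_dataset):
        perm = np.random.default_rng(8).permutation(five_level_dataset.n_samples)
        shuffled = ExpressionDataset(
            five_level_dataset.probe_ids, five_level_dataset.values[:, perm],
            five_level_dataset.doses[perm], 2,
            [five_level_dataset.sample_ids[i] for i in perm])
        s = FilterSettings(2.0, 0.05, "williams", resampling_count=200, seed=9)
        a = screen_probes(five_level_dataset, s)
        b = screen_probes(shuffled, s)
        np.testing.assert_allclose(a["fold_change"], b["fold_change"])
        np.testing.assert_allclose(a["p_anova"], b["p_anova"], atol=1e-12)
        np.testing.assert_allclose(a["p_williams"], b["p_williams"], atol=1e-12)
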