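import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from micronova.stats import (
    SeparationError,
    crosstab_chi2,
    fit_logistic,
    kruskal_wallis,
    letter_display,
    mann_whitney,
    median_split,
    pairwise_bonferroni,
    quartile_assign,
    summarise_groups,
)
from micronova.synth import simulate_logistic_outcomes

# ---------------------------------------------------------------- oracles


def enumerate_kw_p(data, labels):
    """Brute-force permutation p for Kruskal-Wallis via scipy on every split."""
    data = np.asarray(data, float)
    labels = np.asarray(labels)
    uniq = list(pd.unique(labels))
    obs = sps.kruskal(*[data[labels == g] for g in uniq]).statistic
    count = total = 0
    for perm in set(itertools.permutations(labels)):
        perm = np.asarray(perm)
        h = sps.kruskal(*[data[perm == g] for g in uniq]).statistic
        total += 1
        if h >= obs - 1e-9:
            count += 1
    return count / total


def enumerate_mw_p(a, b):
    """Brute-force two-sided permutation p for Mann-Whitney U."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    mid = n1 * len(b) / 2
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mid) >= abs(u_obs - mid) - 1e-9:
            count += 1
    return count / total


# ---------------------------------------------------------------- tests


class TestSummaries:
    def test_median_and_iqr_of_small_sample(self):
        (s,) = summarise_groups([1, 2, 3, 4, 5], ["g"] * 5)
        assert (s.median, s.q25, s.q75) == (3.0, 2.0, 4.0)

    def test_constant_scores_have_zero_iqr_width(self):
        (s,) = summarise_groups([7.0] * 10, ["g"] * 10)
        assert s.median == s.q25 == s.q75 == 7.0

    def test_identical_groups_get_identical_summaries(self):
        scores = [1, 5, 9, 1, 5, 9]
        a, b = summarise_groups(scores, ["x", "x", "x", "y", "y", "y"])
        assert (a.median, a.q25, a.q75) == (b.median, b.q25, b.q75)


class TestKruskalWallis:
    def test_constant_data_gives_h_zero_p_one(self):
        r = kruskal_wallis([4.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert r.statistic == 0.0 and r.p == 1.0

    def test_h_matches_hand_rank_computation(self):
        # groups {1,2,3},{4,5,6},{7,8,9}: rank sums 6,15,24;
        # H = 12/(9*10) * (36/3 + 225/3 + 576/3) - 3*10 = 7.2
        r = kruskal_wallis(range(1, 10), ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert r.statistic == pytest.approx(7.2)
        assert r.df == 2

    @pytest.mark.parametrize(
        "data,sizes",
        [
            (list(range(1, 9)), (3, 3, 2)),
            (list(range(1, 7)), (2, 2, 2)),
            ([1, 1, 2, 2, 3, 3, 4, 4], (3, 3, 2)),  # heavy ties
        ],
    )
    def test_small_sample_p_equals_exhaustive_enumeration(self, data, sizes):
        labels = np.repeat([f"g{i}" for i in range(len(sizes))], sizes)
        r = kruskal_wallis(data, labels)
        assert r.method == "kruskal-wallis exact"
        assert r.p == pytest.approx(enumerate_kw_p(data, labels), abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], ["a"] * 3)

    def test_large_groups_take_the_chi2_path(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=300)
        labels = np.repeat(["a", "b", "c"], 100)
        r = kruskal_wallis(scores, labels)
        assert r.method == "kruskal-wallis chi2"
        ref = sps.kruskal(scores[:100], scores[100:200], scores[200:])
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue)


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        r = mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0])
        assert r.p == 1.0

    def test_complete_separation_gives_u_zero(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0

    @pytest.mark.parametrize(
        "a,b",
        [
            ([1, 4, 2, 7], [3, 5, 6, 8]),
            ([1, 1, 2, 3], [2, 2, 3, 4]),  # ties
            ([10, 12], [11, 13, 14, 15, 9]),
        ],
    )
    def test_small_sample_p_equals_exhaustive_enumeration(self, a, b):
        r = mann_whitney(a, b)
        assert r.method == "mann-whitney exact"
        assert r.p == pytest.approx(enumerate_mw_p(np.array(a, float), np.array(b, float)), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_two_group_kw_agrees_with_mw_up_to_continuity_correction(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 120)
        b = rng.normal(0.3, 1, 150)
        scores = np.concatenate([a, b])
        labels = np.array(["a"] * 120 + ["b"] * 150)
        p_kw = kruskal_wallis(scores, labels, method="asymptotic").p
        p_mw = mann_whitney(a, b, method="asymptotic").p
        # both are midrank tests; they differ only by the continuity correction
        assert p_kw == pytest.approx(p_mw, abs=0.01)


class TestPairwise:
    def test_four_groups_give_six_comparisons_with_multiplier_six(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40)
        labels = np.repeat(["a", "b", "c", "d"], 10)
        results = pairwise_bonferroni(scores, labels, method="asymptotic")
        assert len(results) == 6
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p * 6))

    def test_adjusted_p_capped_at_one(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        labels = np.repeat(["a", "b", "c", "d"], 10)
        results = pairwise_bonferroni(scores, labels, method="asymptotic")
        assert all(r.p_adjusted <= 1.0 for r in results)
        assert all(r.p_adjusted >= r.p for r in results)

    def test_identical_groups_share_a_letter_distinct_group_does_not(self):
        base = list(range(1, 21))
        scores = base + base + [x + 100 for x in base]
        labels = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        results = pairwise_bonferroni(scores, labels, method="asymptotic")
        letters = letter_display(["a", "b", "c"], results)
        assert set(letters["a"]) & set(letters["b"])
        assert not set(letters["a"]) & set(letters["c"])


class TestQuartiles:
    def test_uniform_scores_split_evenly(self):
        labels = quartile_assign(np.arange(1, 101, dtype=float))
        counts = pd.Series(labels).value_counts()
        assert counts.tolist() == [25, 25, 25, 25]

    def test_value_at_cut_goes_to_lower_quartile(self):
        scores = np.arange(1, 9, dtype=float)  # q25 = 2.75, q50 = 4.5, q75 = 6.25
        scores[1] = 2.75
        labels = quartile_assign(scores)
        assert labels[1] == "Q1"

    def test_labels_partition_the_items(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=997)
        labels = quartile_assign(scores)
        assert pd.Series(labels).value_counts().sum() == 997

    def test_constant_scores_collapse_with_warning(self):
        with pytest.warns(UserWarning):
            labels = quartile_assign(np.ones(10))
        assert set(labels) == {"Q1"}


class TestChi2:
    def test_perfect_association_on_2x2_equals_n(self):
        rows = ["x"] * 30 + ["y"] * 30
        cols = ["p"] * 30 + ["q"] * 30
        table, r = crosstab_chi2(rows, cols)
        assert r.statistic == pytest.approx(60.0)  # chi2 = n (min(r,c)-1)
        assert table.to_numpy().sum() == 60

    def test_independent_labels_not_extreme(self):
        rng = np.random.default_rng(11)
        rows = rng.choice(["a", "b", "c", "d"], 2000)
        cols = rng.choice(["x", "y"], 2000)
        _, r = crosstab_chi2(rows, cols)
        assert r.p > 0.001

    def test_margins_conserve_n(self):
        rng = np.random.default_rng(4)
        rows = rng.choice(["a", "b"], 500)
        cols = rng.choice(["x", "y", "z"], 500)
        table, r = crosstab_chi2(rows, cols)
        assert table.to_numpy().sum() == 500
        assert r.df == 2

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            crosstab_chi2(["a"] * 10, ["x"] * 5 + ["y"] * 5)


class TestMedianSplit:
    def test_strictly_above_rule(self):
        assert median_split([1, 2, 3]).tolist() == [0.0, 0.0, 1.0]

    def test_all_equal_scores_are_all_below_or_at(self):
        assert median_split([5, 5, 5, 5]).tolist() == [0.0] * 4

    def test_half_strictly_above(self):
        out = median_split([1, 1, 1, 9, 9, 9])
        assert out.tolist() == [0, 0, 0, 1, 1, 1]


class TestLogistic:
    def test_null_data_cis_cover_or_one(self):
        sim = simulate_logistic_outcomes(4000, {}, seed=5)
        fit = fit_logistic(sim["outcome"], sim["nova"], sim["healthy"])
        for term in fit.terms.index:
            if term == "intercept":
                continue
            _, lo, hi = fit.odds_ratio(term)
            assert lo < 1.0 < hi

    def test_known_or_recovered_within_ci(self):
        sim = simulate_logistic_outcomes(5000, {"nova_UPF": -1.0}, seed=8)
        fit = fit_logistic(sim["outcome"], sim["nova"], sim["healthy"])
        or_, lo, hi = fit.odds_ratio("nova_UPF")
        assert lo <= np.exp(-1.0) <= hi
        inv, ilo, ihi = fit.inverse_odds_ratio("nova_UPF")
        assert inv == pytest.approx(1 / or_)
        assert ilo <= np.e <= ihi

    def test_single_covariate_model_matches_2x2_cross_product_ratio(self):
        rng = np.random.default_rng(9)
        nova = rng.choice(["MPF", "UPF"], 600)
        outcome = np.where(
            nova == "UPF", rng.random(600) < 0.3, rng.random(600) < 0.55
        ).astype(float)
        fit = fit_logistic(outcome, nova, np.ones(600, bool))
        a = np.sum((nova == "UPF") & (outcome == 1))
        b = np.sum((nova == "UPF") & (outcome == 0))
        c = np.sum((nova == "MPF") & (outcome == 1))
        d = np.sum((nova == "MPF") & (outcome == 0))
        assert fit.odds_ratio("nova_UPF")[0] == pytest.approx((a * d) / (b * c))

    def test_complete_separation_is_named(self):
        nova = np.array(["MPF", "UPF"] * 50)
        outcome = (nova == "UPF").astype(float)
        with pytest.raises(SeparationError, match="nova_UPF"):
            fit_logistic(outcome, nova, np.ones(100, bool))

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic([0.0, 0.5, 1.0], ["MPF"] * 3, [True] * 3)
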