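"""Cohort statistics: AUC, permutation/binomial tests, normalization,
composite search, fold changes, correlation, power and precision CVs."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from speckpull import (
    CohortSpec,
    CompositeExpression,
    PowerSpec,
    auc,
    binomial_group_size_test,
    composite_search,
    correlate,
    cv_precision,
    evaluate_composite,
    fold_change,
    group_max_normalize,
    permutation_exact_test,
    power_two_sample_t,
    simulate_cohort,
)
from speckpull.biomarker import cohort_to_wide, enumerate_expressions

from conftest import brute_force_auc, brute_force_permutation_p


class TestAuc:
    def test_perfect_separation_and_all_ties(self):
        assert auc([3, 4, 5, 0, 1, 2], [1, 1, 1, 0, 0, 0]) == 1.0
        assert auc([5, 5, 5, 5], [1, 1, 0, 0]) == 0.5

    def test_small_example_by_pair_enumeration(self):
        # disease {3,5,7} vs control {1,2,6}: 7 wins, 0 ties out of 9 pairs
        scores = [3, 5, 7, 1, 2, 6]
        labels = [1, 1, 1, 0, 0, 0]
        assert auc(scores, labels) == pytest.approx(7 / 9)
        assert brute_force_auc(np.array([3, 5, 7]),
                               np.array([1, 2, 6])) == pytest.approx(7 / 9)

    def test_matches_pairwise_brute_force_on_random_cohorts(self, rng):
        for _ in range(50):
            n_pos = rng.integers(2, 8)
            n_neg = rng.integers(2, 8)
            pos = rng.integers(0, 10, n_pos).astype(float)
            neg = rng.integers(0, 10, n_neg).astype(float)
            scores = np.concatenate([pos, neg])
            labels = np.r_[np.ones(n_pos), np.zeros(n_neg)]
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(pos, neg))

    def test_complement_identity_for_tie_free_scores(self, rng):
        scores = rng.permutation(20).astype(float)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]  # both classes present
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2, 3], [1, 1, 1])


class TestPermutationTest:
    def test_constant_samples_give_p_one(self):
        assert permutation_exact_test([2, 2, 2], [2, 2, 2]) == 1.0

    def test_fully_separated_three_vs_three(self):
        # only the observed split and its mirror reach |delta| = 9
        assert permutation_exact_test([1, 2, 3], [10, 11, 12]) == \
            pytest.approx(2 / 20)

    def test_exact_matches_bitmask_oracle_up_to_6v6(self, rng):
        for n, m in [(2, 2), (3, 3), (3, 5), (4, 4), (6, 6)]:
            x = rng.integers(0, 20, n).astype(float)
            y = rng.integers(0, 20, m).astype(float)
            assert permutation_exact_test(x, y) == pytest.approx(
                brute_force_permutation_p(x, y))

    def test_monte_carlo_agrees_with_exact(self, rng):
        x = rng.normal(1.0, 1.0, 5)
        y = rng.normal(0.0, 1.0, 5)
        p_exact = permutation_exact_test(x, y)
        p_mc = permutation_exact_test(x, y, max_exact=10, n_resamples=20000,
                                      seed=0)
        se = np.sqrt(p_exact * (1 - p_exact) / 20000)
        assert abs(p_mc - p_exact) < 3 * se + 1e-4

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 10))
    @hyp_settings(max_examples=20, deadline=None)
    def test_invariant_to_shift_and_positive_scale(self, shift, scale):
        x = np.array([1.0, 3.0, 4.0, 8.0])
        y = np.array([2.0, 5.0, 9.0])
        p0 = permutation_exact_test(x, y)
        p1 = permutation_exact_test(x * scale + shift, y * scale + shift)
        assert p0 == pytest.approx(p1)


class TestBinomialGroupSizeTest:
    def test_balanced_sizes(self):
        assert binomial_group_size_test(10, 10) == 1.0

    def test_thirty_vs_twenty(self):
        # exact two-sided tail sum; reported as 0.2
        p = binomial_group_size_test(30, 20)
        tail = sum(comb(50, k) * 0.5 ** 50 for k in range(30, 51))
        other = sum(comb(50, k) * 0.5 ** 50 for k in range(0, 21))
        assert p == pytest.approx(tail + other)
        assert round(p, 1) == 0.2

    def test_extreme_split(self):
        assert binomial_group_size_test(0, 8) == pytest.approx(2 * 0.5 ** 8)


class TestGroupMaxNormalize:
    def test_single_group(self):
        with pytest.warns(UserWarning, match="leak"):
            out = group_max_normalize([2, 4, 8], ["a", "a", "a"])
        assert out.tolist() == [0.25, 0.5, 1.0]

    def test_each_group_attains_one(self):
        with pytest.warns(UserWarning):
            out = group_max_normalize([2, 4, 10, 5], ["a", "a", "b", "b"])
        assert out[1] == 1.0 and out[2] == 1.0

    def test_all_equal_normalizes_to_one(self):
        with pytest.warns(UserWarning):
            out = group_max_normalize([3, 3, 3], ["a", "a", "b"])
        assert (out == 1.0).all()

    def test_nonpositive_group_max_rejected(self):
        with pytest.warns(UserWarning), pytest.raises(ValueError):
            group_max_normalize([0, 0], ["a", "a"])


def toy_wide():
    return pd.DataFrame({
        "subject": ["s1", "s2", "s3"],
        "group": ["disease", "disease", "control"],
        "ASC": [6.0, 8.0, 2.0],
        "ptau": [4.0, 2.0, 1.0],
        "Abeta": [2.0, 4.0, 2.0],
    })


class TestEvaluateComposite:
    def test_single_marker_identity(self):
        wide = toy_wide()
        e = CompositeExpression("m", ("ASC",))
        assert evaluate_composite(e, wide).tolist() == [6.0, 8.0, 2.0]

    def test_sum_ratio_arithmetic(self):
        wide = toy_wide()
        e = CompositeExpression("(m1+m2)/m3", ("ptau", "ASC", "Abeta"))
        assert evaluate_composite(e, wide)[0] == pytest.approx((4 + 6) / 2)

    def test_missing_marker_names_subject(self):
        wide = toy_wide()
        wide.loc[1, "ptau"] = np.nan
        e = CompositeExpression("m1/m2", ("ptau", "Abeta"))
        with pytest.raises(ValueError, match="s2"):
            evaluate_composite(e, wide)
        with pytest.raises(KeyError, match="missing"):
            evaluate_composite(CompositeExpression("m", ("nope",)), wide)

    def test_group_max_normalization_is_scale_invariant(self):
        wide = toy_wide()
        e = CompositeExpression("(m1+m2)/m3", ("ptau", "ASC", "Abeta"),
                                normalize_denominator=True)
        with pytest.warns(UserWarning):
            s1 = evaluate_composite(e, wide)
        wide2 = wide.copy()
        # double Abeta within the disease group only
        sel = wide2["group"] == "disease"
        wide2.loc[sel, "Abeta"] *= 2.0
        with pytest.warns(UserWarning):
            s2 = evaluate_composite(e, wide2)
        np.testing.assert_allclose(s1, s2)


class TestCompositeSearch:
    def test_grammar_enumeration_count(self):
        # k + C(k,2) + k(k-1) + C(k,2)(k-2)
        for k in (2, 3, 4):
            markers = [f"m{i}" for i in range(k)]
            exprs = enumerate_expressions(markers)
            expected = k + comb(k, 2) + k * (k - 1) + comb(k, 2) * (k - 2)
            assert len(exprs) == expected
            assert len({str(e) for e in exprs}) == expected

    def test_single_marker_ranking(self):
        cohort = pd.DataFrame({
            "subject": ["a", "b", "c", "d"],
            "group": ["disease", "disease", "control", "control"],
            "marker": ["ASC"] * 4,
            "value": [5.0, 6.0, 1.0, 2.0]})
        ranking = composite_search(cohort)
        assert ranking["expression"].tolist() == ["ASC"]
        assert ranking["auc"].iloc[0] == 1.0

    def test_planted_ratio_ranks_first(self):
        # disease raises the total burden T, which partitions randomly
        # between m1 and m2 per subject, while m3 only tracks the shared
        # per-subject capture efficiency: the sum m1+m2 undoes the
        # partition noise and dividing by m3 cancels the efficiency, so
        # (m1+m2)/m3 is the uniquely best expression in the grammar
        wins = 0
        n = 20
        for seed in range(100):
            r = np.random.default_rng(seed)
            eff = r.lognormal(0.0, 0.6, 2 * n)
            grp = np.r_[np.zeros(n), np.ones(n)]
            fold = np.where(grp == 1, 1.8, 1.0)
            burden = 60.0 * eff * fold * r.lognormal(0, 0.2, 2 * n)
            q = r.uniform(0.2, 0.8, 2 * n)
            values = {"m1": r.poisson(q * burden) + 1.0,
                      "m2": r.poisson((1 - q) * burden) + 1.0,
                      "m3": r.poisson(50.0 * eff) + 1.0}
            rows = [(f"s{j}", "disease" if grp[j] else "control", mk, v[j])
                    for mk, v in values.items() for j in range(2 * n)]
            cohort = pd.DataFrame(rows, columns=["subject", "group",
                                                 "marker", "value"])
            ranking = composite_search(cohort)
            if ranking["expression"].iloc[0] == "(m1+m2)/m3":
                wins += 1
        assert wins >= 90

    def test_planted_cohort_recovery_of_fold_and_auc(self):
        spec = CohortSpec(n_control=20, n_disease=20,
                          marker_means={"ASC": 40.0},
                          fold_changes={"ASC": 4.2},
                          dispersion=20.0, seed=5)
        cohort, _ = simulate_cohort(spec)
        wide = cohort_to_wide(cohort)
        v = wide["ASC"].to_numpy(float)
        d = wide["group"].to_numpy() == "disease"
        assert auc(v, d) >= 0.85
        assert 3.4 <= fold_change(v[d], v[~d])["mean_fold"] <= 5.0


class TestFoldChange:
    def test_identity_and_exact_doubling(self):
        assert fold_change([4, 4], [4, 4])["mean_fold"] == 1.0
        assert fold_change([8, 8], [4, 4])["mean_fold"] == 2.0

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValueError):
            fold_change([1, 2], [0, 0])


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert correlate(x, x)[0] == pytest.approx(1.0)
        assert correlate(x, -x)[0] == pytest.approx(-1.0)

    def test_monotone_nonlinearity(self):
        x = np.arange(1.0, 11.0)
        y = np.exp(x)
        r_s, _ = correlate(x, y, "spearman")
        r_p, _ = correlate(x, y, "pearson")
        assert r_s == pytest.approx(1.0)
        assert r_p < 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1], [1, 2, 3])


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert power_two_sample_t(PowerSpec(d_cohen=0.0)) == \
            pytest.approx(0.05, abs=1e-10)

    def test_design_point_rounds_to_99_percent(self):
        power = power_two_sample_t(PowerSpec(d_cohen=2.0, n_per_group=10,
                                             alpha=0.05))
        assert round(100 * power) == 99

    def test_matches_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower
        for d, n in [(0.5, 20), (1.0, 12), (2.0, 10)]:
            ours = power_two_sample_t(PowerSpec(d_cohen=d, n_per_group=n))
            ref = TTestIndPower().power(effect_size=d, nobs1=n, alpha=0.05)
            assert ours == pytest.approx(ref, abs=1e-6)

    def test_monotone_in_effect_and_sample_size(self):
        grid_d = [0.2, 0.5, 1.0, 2.0]
        powers = [power_two_sample_t(PowerSpec(d_cohen=d)) for d in grid_d]
        assert powers == sorted(powers)
        grid_n = [5, 10, 20, 40]
        powers = [power_two_sample_t(PowerSpec(d_cohen=0.8, n_per_group=n))
                  for n in grid_n]
        assert powers == sorted(powers)


class TestCvPrecision:
    def test_identical_replicates_cv_zero(self):
        df = pd.DataFrame({"sample": ["a"] * 2, "plate": [1, 1],
                           "value": [100.0, 100.0]})
        assert cv_precision(df)["intra_cv_pct"] == 0.0

    def test_two_point_cv_arithmetic(self):
        df = pd.DataFrame({"sample": ["a"] * 2, "plate": [1, 1],
                           "value": [90.0, 110.0]})
        assert cv_precision(df)["intra_cv_pct"] == pytest.approx(14.14, abs=0.01)

    def test_lognormal_noise_recovers_inter_cv(self, rng):
        sigma = 0.15
        rows = []
        for s in range(20):
            true = rng.uniform(50, 150)
            for plate in (1, 2):
                rows.append((f"s{s}", plate,
                             true * rng.lognormal(0, sigma)))
        df = pd.DataFrame(rows, columns=["sample", "plate", "value"])
        out = cv_precision(df)
        assert abs(out["inter_cv_pct"] - 15.0) < 5.0
        assert out["acceptable"]

    def test_zero_mean_rejected(self):
        df = pd.DataFrame({"sample": ["a"] * 2, "plate": [1, 1],
                           "value": [0.0, 0.0]})
        with pytest.raises(ValueError):
            cv_precision(df)
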