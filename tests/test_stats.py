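"""Survey statistics: censoring, rank sums, permutation regression, PCA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.decomposition import PCA as SkPCA

from winternit import (
    compare_rate_groups,
    group_median,
    partition_by_rate,
    pca,
    permutation_regression,
    rank_sum_test,
    regression_dataset,
    summarize,
)


def exact_rank_sum_p(a, b):
    """Independent oracle: full enumeration of rank assignments.

    Two-sided p as the probability, under the permutation null, that the
    Mann-Whitney U of group a is at least as extreme as observed.
    """
    pooled = sorted(a) + sorted(b)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}

    def u_of(group_ranks, n1, n2):
        return sum(group_ranks) - n1 * (n1 + 1) / 2

    n1, n2 = len(a), len(b)
    all_ranks = [ranks[v] for v in pooled]
    observed = u_of([ranks[v] for v in a], n1, n2)
    mid = n1 * n2 / 2
    count = 0
    total = 0
    for combo in itertools.combinations(all_ranks, n1):
        total += 1
        if abs(u_of(combo, n1, n2) - mid) >= abs(observed - mid) - 1e-12:
            count += 1
    return count / total


class TestRankSum:
    def test_separated_groups_enumeration(self):
        _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_p_one(self):
        _, p = rank_sum_test([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    @given(
        a=st.lists(st.integers(0, 1000), min_size=2, max_size=8, unique=True),
        b=st.lists(st.integers(2000, 3000), min_size=2, max_size=8, unique=True),
        shift=st.integers(-1500, 500),
    )
    @settings(max_examples=40, deadline=None)
    def test_exact_branch_equals_enumeration(self, a, b, shift):
        b = [v + shift for v in b]
        if set(a) & set(b):
            return
        _, p = rank_sum_test(a, b)
        assert p == pytest.approx(exact_rank_sum_p(a, b), abs=1e-9)


class TestGroupMedians:
    @given(
        values=st.lists(
            st.floats(-1e3, 1e3, allow_nan=False), min_size=1, max_size=30
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_sort_based_oracle(self, values):
        frame = pd.DataFrame({"oxygen": values})
        ordered = sorted(values)
        k = len(ordered)
        oracle = (
            ordered[k // 2]
            if k % 2
            else (ordered[k // 2 - 1] + ordered[k // 2]) / 2
        )
        assert group_median(frame, "oxygen", "keep") == pytest.approx(
            oracle, abs=1e-9
        )

    def test_empty_after_policy_is_error(self):
        frame = pd.DataFrame(
            {"ammonium": [40.0], "ammonium_below_mdl": [True]}
        )
        with pytest.raises(ValueError):
            group_median(frame, "ammonium", "exclude")


class TestPartition:
    def test_study_lakes_partition(self, study_lakes):
        high, low = partition_by_rate(study_lakes)
        assert sorted(high["location"]) == [
            "ELA Lake 227",
            "Echo Lake",
            "Katepwa Lake",
            "Mission Lake",
            "Pasqua Lake",
            "St. Brieux Lake",
        ]
        assert len(low) == 7
        # the low group is exactly the substituted censored values
        assert (low["censored_rate"] == 0.11).all()

    def test_all_below_threshold_empty_high(self):
        frame = pd.DataFrame(
            {"rate": [0.01, -0.5], "location": ["a", "b"], "season": "winter_ice"}
        )
        high, low = partition_by_rate(frame)
        assert high.empty and len(low) == 2

    def test_zero_threshold_on_positive_rates(self):
        frame = pd.DataFrame(
            {"rate": [0.5, 1.0], "location": ["a", "b"], "season": "winter_ice"}
        )
        high, low = partition_by_rate(frame, threshold=0.0)
        assert len(high) == 2 and low.empty

    def test_missing_rates_excluded(self, survey):
        high, low = partition_by_rate(survey)
        assert len(high) + len(low) == survey["rate"].notna().sum()


class TestPermutationRegression:
    def test_coefficients_match_ols_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1000, 25)
        y = rng.lognormal(0.5, 1.0, 25)
        fit = permutation_regression(x, y, n_perm=99, seed=0)
        design = sm.add_constant(x - x.mean())
        oracle = sm.OLS(np.log10(y + 1), design).fit()
        assert fit.intercept == pytest.approx(oracle.params[0], abs=1e-10)
        assert fit.slope == pytest.approx(oracle.params[1], abs=1e-10)
        assert fit.r2 == pytest.approx(oracle.rsquared, abs=1e-10)
        assert fit.adjusted_r2 == pytest.approx(oracle.rsquared_adj, abs=1e-10)
        assert fit.df == oracle.df_resid

    def test_perfect_fit(self):
        x = np.arange(10.0)
        y = 10.0 ** (0.01 * x + 0.2) - 1.0  # transform-exact line
        fit = permutation_regression(x, y, n_perm=199, seed=0)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.permutation_p == pytest.approx(1 / 200)

    def test_slope_invariant_to_centering(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 500, 20)
        y = rng.lognormal(0.0, 0.8, 20)
        centered = permutation_regression(x, y, center=True, n_perm=19, seed=0)
        raw = permutation_regression(x, y, center=False, n_perm=19, seed=0)
        assert centered.slope == pytest.approx(raw.slope, rel=1e-12)
        assert centered.intercept == pytest.approx(
            np.log10(y + 1).mean(), abs=1e-12
        )

    def test_p_stable_across_seeds(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1000, 15)
        y = 10.0 ** (0.0008 * x + 0.1 + rng.normal(0, 0.4, 15)) - 1
        n_perm = 5000
        p1 = permutation_regression(x, y, n_perm=n_perm, seed=1).permutation_p
        p2 = permutation_regression(x, y, n_perm=n_perm, seed=2).permutation_p
        se = math.sqrt(p1 * (1 - p1) / n_perm)
        assert abs(p1 - p2) <= 2 * se + 1e-9

    def test_null_p_roughly_uniform(self):
        # under a permuted (null) predictor, p should not concentrate low
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(30):
            x = rng.uniform(0, 1000, 12)
            y = rng.lognormal(0.3, 0.5, 12)
            ps.append(
                permutation_regression(x, y, n_perm=199, seed=0).permutation_p
            )
        assert 0.2 < np.mean(ps) < 0.8
        assert sum(p < 0.05 for p in ps) <= 6

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            permutation_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], n_perm=9)


class TestSummarize:
    def test_single_record_degenerate(self):
        frame = pd.DataFrame(
            {
                "season": ["winter_ice"],
                "rate": [1.5],
                "rate_below_sample_loq": [False],
                "oxygen": [7.0],
            }
        )
        table = summarize(frame, variables=("rate", "oxygen"))
        assert (table.loc["minimum"] == table.loc["maximum"]).all()
        assert table.loc["median", "rate"] == 1.5

    def test_summer_rows_excluded(self, survey):
        table = summarize(survey, variables=("rate",))
        # summer minimum (0.11 at Lake Superior) must not drive the footer
        assert table.loc["minimum", "rate"] == pytest.approx(0.022)


class TestRegressionDataset:
    def test_subset_sizes(self, survey):
        assert regression_dataset(survey, "all")[0].size == 22
        assert regression_dataset(survey, "no_pasqua")[0].size == 21
        assert regression_dataset(survey, "literature")[0].size == 9

    def test_study_rates_censored_literature_raw(self, survey):
        _, rates = regression_dataset(survey, "all")
        assert rates.min() == pytest.approx(0.03)  # Superior, uncensored
        assert np.sum(rates == 0.11) == 7  # the censored study records


class TestPca:
    def test_orthonormal_loadings_and_variance_sum(self, study_lakes):
        result = pca(
            study_lakes,
            ["rate", "ammonium", "nitrate", "oxygen", "ph"],
        )
        gram = result.loadings.to_numpy().T @ result.loadings.to_numpy()
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-10)
        assert result.variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)

    def test_perfectly_correlated_pair(self):
        x = np.arange(1.0, 11.0)
        frame = pd.DataFrame({"a": x, "b": 3 * x + 2})
        result = pca(frame, ["a", "b"])
        assert result.variance_fraction[0] == pytest.approx(1.0, abs=1e-10)

    def test_independent_variables_share_variance(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.normal(size=(4000, 4)), columns=list("abcd"))
        result = pca(frame, list("abcd"))
        assert np.allclose(result.variance_fraction, 0.25, atol=0.03)

    def test_matches_sklearn(self, study_lakes):
        variables = ["rate", "ammonium", "nitrate", "oxygen", "ph"]
        result = pca(study_lakes, variables)
        data = study_lakes[variables].dropna().to_numpy(dtype=float)
        scaled = (data - data.mean(0)) / data.std(0, ddof=1)
        oracle = SkPCA().fit(scaled)
        assert np.allclose(
            result.variance_fraction, oracle.explained_variance_ratio_, atol=1e-10
        )
        for j in range(len(variables)):
            ours = result.loadings.iloc[:, j].to_numpy()
            theirs = oracle.components_[j]
            assert np.allclose(ours, theirs, atol=1e-8) or np.allclose(
                ours, -theirs, atol=1e-8
            )

    def test_constant_variable_named_in_error(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="b"):
            pca(frame, ["a", "b"])


class TestCompareGroups:
    def test_methane_not_separated_by_rate_group(self, study_lakes):
        result = compare_rate_groups(study_lakes, "ch4_saturation")
        assert result.p_value > 0.05
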