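"""Chained-equations imputation engine and its validation procedures."""

import numpy as np
import pandas as pd
import pytest

from pharmacotyping.imputation import (ImputationSet, compare_coefficients,
                                       compare_distributions, impute_chained,
                                       loo_validate)


class TestImputeChained:
    def test_complete_matrix_returned_unchanged(self, rng):
        df = pd.DataFrame(rng.uniform(0, 1, (20, 4)), columns=list("abcd"))
        imp = impute_chained(df, m=3, seed=0)
        for d in imp.datasets:
            pd.testing.assert_frame_equal(d, df)

    def test_observed_cells_never_altered(self, mvn_missing):
        df, X, mask = mvn_missing(0)
        imp = impute_chained(df, m=4, seed=1)
        obs = ~mask
        for d in imp.datasets:
            np.testing.assert_array_equal(d.to_numpy()[obs], X[obs])

    def test_reproducible_and_seed_sensitive(self, mvn_missing):
        df, _, _ = mvn_missing(3)
        a = impute_chained(df, m=3, seed=42)
        b = impute_chained(df, m=3, seed=42)
        c = impute_chained(df, m=3, seed=43)
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da, db)
        assert not a.datasets[0].equals(c.datasets[0])

    def test_pmm_draws_stay_within_observed_range(self, small_cohort):
        imp = impute_chained(small_cohort.observed_lc50, m=3, seed=5)
        for d in imp.datasets:
            arr = d.to_numpy()
            assert np.isfinite(arr).all()
            assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_beats_median_fill_on_correlated_data(self, small_cohort):
        obs = small_cohort.observed_lc50
        truth = small_cohort.true_lc50.to_numpy()
        mask = obs.isna().to_numpy()
        imp = impute_chained(obs, m=10, seed=2)
        pooled = sum(d.to_numpy() for d in imp.datasets) / imp.m
        mae_pmm = np.abs(pooled[mask] - truth[mask]).mean()
        mae_median = np.abs(
            obs.fillna(obs.median()).to_numpy()[mask] - truth[mask]).mean()
        assert mae_pmm < mae_median

    def test_single_column_is_error(self):
        df = pd.DataFrame({"a": [0.1, np.nan, 0.3] * 5})
        with pytest.raises(ValueError, match="2"):
            impute_chained(df, m=2, seed=0)

    def test_all_missing_row_is_error(self, rng):
        df = pd.DataFrame(rng.uniform(0, 1, (15, 3)), columns=list("abc"))
        df.iloc[2, :] = np.nan
        with pytest.raises(ValueError, match="all-missing"):
            impute_chained(df, m=2, seed=0)

    def test_thin_column_policy(self, rng):
        df = pd.DataFrame(rng.uniform(0, 1, (30, 3)), columns=list("abc"))
        df.loc[df.index[:28], "c"] = np.nan     # only 2 observed
        df.iloc[0, 0] = np.nan
        with pytest.warns(UserWarning, match="threshold"):
            impute_chained(df, m=2, seed=0, on_thin_column="warn")
        with pytest.raises(ValueError, match="threshold"):
            impute_chained(df, m=2, seed=0, on_thin_column="error")

    def test_stacked_shape(self, mvn_missing):
        df, _, _ = mvn_missing(1)
        imp = impute_chained(df, m=5, seed=0)
        assert imp.stacked().shape == (5 * len(df), df.shape[1])


class TestLooValidation:
    def test_exact_linear_dependency_recovered(self, rng):
        x = rng.uniform(0, 1, 60)
        df = pd.DataFrame({"a": x, "b": 0.8 * x + 0.1,
                           "c": rng.uniform(0, 1, 60)})
        report = loo_validate(df, m=10, seed=0, max_cells=20)
        cells_b = report.cells[report.cells["drug_id"] == "b"]
        if not cells_b.empty:
            err = (cells_b["imputed_mean"] - cells_b["observed"]).abs()
            assert err.max() < 0.05
            assert cells_b["covered"].all()
        assert 0.0 <= report.coverage <= 1.0
        assert (report.cells["ci_low"] <= report.cells["imputed_mean"]).all()
        assert (report.cells["imputed_mean"] <= report.cells["ci_high"]).all()

    def test_subsample_larger_than_observed_is_error(self, rng):
        df = pd.DataFrame(rng.uniform(0, 1, (10, 3)))
        with pytest.raises(ValueError, match="subsample"):
            loo_validate(df, m=3, seed=0, max_cells=1000)

    def test_single_column_is_error(self):
        with pytest.raises(ValueError):
            loo_validate(pd.DataFrame({"a": [0.5, 0.6]}), m=3, seed=0)


class TestCompareDistributions:
    def _null_case(self, seed, shift=0.0, n=400, p=4):
        g = np.random.default_rng(seed)
        X = g.uniform(0, 1, (n, p))
        mask = g.random((n, p)) < 0.4
        obs = pd.DataFrame(np.where(mask, np.nan, X),
                           columns=[f"d{i}" for i in range(p)])
        datasets = []
        for _ in range(3):
            filled = obs.copy()
            fill = np.clip(g.uniform(0, 1, (n, p)) + shift, 0, 1)
            filled[:] = np.where(mask, fill, X)
            datasets.append(filled)
        return obs, ImputationSet(datasets, seed=0, iterations=0)

    def test_same_distribution_not_significant(self):
        obs, imp = self._null_case(0)
        out = compare_distributions(obs, imp)
        assert (out["p_bh"] > 0.05).all()

    def test_shifted_imputations_detected(self):
        obs, imp = self._null_case(1, shift=0.5)
        out = compare_distributions(obs, imp)
        assert (out["p_bh"] < 0.05).all()

    def test_identical_vectors_statistic_zero(self, rng):
        X = rng.uniform(0, 1, (200, 2))
        obs = pd.DataFrame(X, columns=["a", "b"])
        obs.iloc[:100, 0] = np.nan
        datasets = [pd.DataFrame(X, columns=["a", "b"])]
        # imputed values exactly equal the held-out observed distribution
        out = compare_distributions(obs, ImputationSet(datasets, 0, 0))
        assert np.isfinite(out.loc[out["drug_id"] == "a", "chi2"]).all()


class TestCompareCoefficients:
    def _setting(self, rng, n=150, p=5):
        X = rng.uniform(0, 1, (n, p))
        betas = np.linspace(-0.3, 0.5, p)
        cov = pd.DataFrame({"protocol": rng.choice(["A", "B"], n),
                            "age": rng.uniform(1, 18, n),
                            "wbc": 10 ** rng.normal(1.2, 0.4, n)})
        df = pd.DataFrame(X, columns=[f"d{i}" for i in range(p)])
        mrd = pd.Series(X @ betas * 0 + X[:, 0] * 0, index=df.index)
        # per-drug univariate signal: each column contributes its own beta
        mrd = pd.Series(-1.0 + (X * betas).sum(1) + rng.normal(0, 0.2, n),
                        index=df.index)
        return df, mrd, cov

    def test_identical_copies_give_r_one(self, rng):
        df, mrd, cov = self._setting(rng)
        imp = ImputationSet([df.copy() for _ in range(4)], 0, 0)
        table, r = compare_coefficients(df, imp, mrd, cov)
        assert r == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(table["beta_measured"], table["beta_imputed"])

    def test_constant_betas_flagged_undefined(self, rng):
        n = 100
        df = pd.DataFrame({"d0": np.full(n, 0.5), "d1": np.full(n, 0.5),
                           "d2": np.full(n, 0.5)})
        mrd = pd.Series(rng.normal(size=n))
        imp = ImputationSet([df.copy()], 0, 0)
        with pytest.warns(UserWarning, match="undefined"):
            _, r = compare_coefficients(df, imp, mrd, None)
        assert np.isnan(r)
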