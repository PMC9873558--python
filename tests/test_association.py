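"""Regression semantics, nonparametric group tests and BH correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pharmacotyping.association import (
    bh_adjust, compare_groups, interpret_beta, regress_lc50_on_mrd,
    trend_across_mrd_groups,
)


def _toy_regression_data(rng, n=60, beta=0.4):
    lc50 = rng.uniform(0, 1, n)
    cov = pd.DataFrame({
        "protocol": rng.choice(["A", "B"], n),
        "age": rng.uniform(1, 18, n),
        "wbc": 10.0 ** rng.normal(1.2, 0.5, n),
    })
    mrd = -1.0 + beta * lc50 + 0.05 * cov["age"].to_numpy() + rng.normal(0, 0.3, n)
    return pd.Series(lc50, name="drugX"), pd.Series(mrd), cov


class TestRegression:
    def test_beta_matches_normal_equations_oracle(self, rng):
        lc50, mrd, cov = _toy_regression_data(rng)
        res = regress_lc50_on_mrd(lc50, mrd, cov, log_wbc=True)
        # independent oracle: solve the normal equations by hand
        X = np.column_stack([
            np.ones(len(lc50)), lc50,
            cov["age"], np.log10(cov["wbc"]),
            (cov["protocol"] == "B").astype(float),
        ])
        beta_hat = np.linalg.solve(X.T @ X, X.T @ mrd.to_numpy())
        assert res.beta == pytest.approx(beta_hat[1], abs=1e-8)
        assert res.ci_low <= res.beta <= res.ci_high
        assert res.n == len(lc50)

    def test_insufficient_n_flagged(self, rng):
        lc50, mrd, cov = _toy_regression_data(rng, n=5)
        res = regress_lc50_on_mrd(lc50, mrd, cov)
        assert res.flag == "insufficient_n"
        assert np.isnan(res.beta)

    def test_constant_predictor_flagged(self, rng):
        _, mrd, cov = _toy_regression_data(rng)
        res = regress_lc50_on_mrd(pd.Series(np.full(len(mrd), 0.5)), mrd, cov)
        assert res.flag == "constant_predictor"

    def test_rank_deficient_design_names_columns(self, rng):
        lc50, mrd, cov = _toy_regression_data(rng)
        cov = cov.assign(age2=cov["age"])  # exact duplicate column
        with pytest.raises(ValueError, match="age"):
            regress_lc50_on_mrd(lc50, mrd, cov)

    def test_null_beta_covers_zero_mostly(self):
        hits = 0
        for seed in range(40):
            g = np.random.default_rng(seed)
            lc50, mrd, cov = _toy_regression_data(g, n=200, beta=0.0)
            res = regress_lc50_on_mrd(lc50, mrd, cov)
            hits += res.ci_low <= 0.0 <= res.ci_high
        assert hits >= 34  # ~95% nominal coverage, generous slack


class TestInterpretBeta:
    def test_paper_equivalences(self):
        assert interpret_beta(np.log10(2.0)) == pytest.approx(2.0, abs=1e-12)
        assert interpret_beta(0.0) == 1.0
        assert interpret_beta(np.log10(0.5)) == pytest.approx(0.5, abs=1e-12)
        assert interpret_beta(0.30) == pytest.approx(2.0, abs=0.005)
        assert interpret_beta(-0.30) == pytest.approx(0.5, abs=0.002)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 100.0))
    def test_identity_on_folds(self, fold):
        assert interpret_beta(np.log10(fold)) == pytest.approx(fold, rel=1e-12)

    def test_nonfinite_is_error(self):
        with pytest.raises(ValueError):
            interpret_beta(float("nan"))


class TestGroupComparisons:
    def test_exact_mann_whitney_enumeration(self):
        # all 20 arrangements of {1..6} into two triples: two-sided p = 2/20
        values = pd.Series([1, 2, 3, 4, 5, 6], dtype=float)
        groups = pd.Series(["a", "a", "a", "b", "b", "b"])
        res = compare_groups(values, groups)
        assert res.test == "mannwhitneyu"
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1)
        assert res.group_medians == {"a": 2.0, "b": 5.0}

    def test_three_groups_use_kruskal(self, rng):
        values = pd.Series(rng.normal(size=30))
        groups = pd.Series(np.repeat(["a", "b", "c"], 10))
        assert compare_groups(values, groups).test == "kruskal"

    def test_single_group_is_error(self):
        with pytest.raises(ValueError):
            compare_groups(pd.Series([1.0, 2, 3]), pd.Series(["a"] * 3))

    def test_all_tied_values_give_p_one(self):
        with pytest.warns(UserWarning):
            res = compare_groups(pd.Series([1.0] * 6),
                                 pd.Series(["a", "a", "a", "b", "b", "b"]))
        assert res.p == 1.0

    def test_type_i_error_calibration(self):
        rejections = 0
        n_sim = 400
        for seed in range(n_sim):
            g = np.random.default_rng(seed)
            values = pd.Series(g.normal(size=40))
            groups = pd.Series(np.repeat(["a", "b"], 20))
            if compare_groups(values, groups).p < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_sim <= 0.08

    def test_trend_across_groups(self, rng):
        groups = pd.Series(np.repeat(np.arange(1, 9), 25))
        values = pd.Series(groups / 8.0 + rng.normal(0, 0.2, len(groups)))
        res = trend_across_mrd_groups(values, groups)
        assert res.p < 0.01
        meds = [res.group_medians[g] for g in range(1, 9)]
        assert meds == sorted(meds)

    def test_trend_degenerate_identical_values(self):
        with pytest.warns(UserWarning):
            res = trend_across_mrd_groups(
                pd.Series([0.5] * 16), pd.Series(np.repeat([1, 2], 8)))
        assert res.p == 1.0


class TestBhAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_properties(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)
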