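"""Normalization, MRD transforms and analysis-table assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pharmacotyping import DEFAULT_PANEL
from pharmacotyping.preprocess import (
    DAY15_CATEGORIES, DAY42_CATEGORIES, Lc50Matrix, MrdMeasurement,
    assign_longitudinal_group, build_analysis_table, categorize_mrd,
    denormalize_minmax, nci_risk, normalize_fold_median, normalize_minmax,
    transform_mrd,
)

DRUGS = DEFAULT_PANEL.drug_ids


class TestMinMaxNormalization:
    def test_left_censor_maps_to_zero(self):
        assert normalize_minmax(0.016, drug_id="asparaginase") == 0.0

    def test_right_censor_maps_to_one(self):
        assert normalize_minmax(20000.0, drug_id="dasatinib") == 1.0

    def test_log_midpoint_maps_to_half(self):
        raw = math.sqrt(0.05 * 20000.0)  # geometric mean of censor bounds
        assert normalize_minmax(raw, drug_id="dasatinib") == pytest.approx(0.5)

    def test_unknown_drug_is_error(self):
        with pytest.raises(KeyError):
            normalize_minmax(1.0, drug_id="aspirin")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0), st.sampled_from(DRUGS))
    def test_round_trip_exact(self, value, drug):
        raw = denormalize_minmax(value, drug_id=drug)
        back = normalize_minmax(raw, drug_id=drug)
        assert back == pytest.approx(value, abs=1e-10)
        again = denormalize_minmax(back, drug_id=drug)
        assert again == pytest.approx(raw, rel=1e-10)

    def test_strictly_increasing_and_rank_agreement(self, rng):
        lo, hi = DEFAULT_PANEL.censor_bounds("prednisolone")
        raw = np.sort(10.0 ** rng.uniform(np.log10(lo), np.log10(hi), 50))
        norm = normalize_minmax(raw, drug_id="prednisolone")
        assert np.all(np.diff(norm) > 0)
        folds = normalize_fold_median(raw)
        assert np.array_equal(np.argsort(norm), np.argsort(folds))

    def test_out_of_bounds_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            v = normalize_minmax(40000.0, drug_id="dasatinib")
        assert v == 1.0


class TestFoldMedianNormalization:
    def test_median_maps_to_zero_and_4x_to_two(self):
        raw = np.array([2.0, 2.0, 8.0])
        out = normalize_fold_median(raw)
        assert out[0] == pytest.approx(0.0)
        assert out[2] == pytest.approx(2.0)

    def test_direct_arithmetic_oracle(self):
        raw = np.array([1.0, 2.0, 4.0, 8.0])     # median 3
        np.testing.assert_allclose(normalize_fold_median(raw), np.log2(raw / 3.0))

    def test_missing_values_ignored_in_median(self):
        raw = np.array([1.0, np.nan, 3.0])
        out = normalize_fold_median(raw)
        assert np.isnan(out[1])
        assert out[0] == pytest.approx(np.log2(1.0 / 2.0))

    def test_all_missing_warns(self):
        with pytest.warns(UserWarning):
            out = normalize_fold_median([np.nan, np.nan])
        assert np.isnan(out).all()


class TestMrd:
    def test_below_lod_uses_half_detection_limit(self):
        assert transform_mrd(0.002) == pytest.approx(math.log10(0.005))
        assert transform_mrd(0.002) == pytest.approx(-2.301, abs=1e-3)

    @pytest.mark.parametrize("raw,expected", [(1.0, 0.0), (5.0, math.log10(5.0))])
    def test_log_transform(self, raw, expected):
        assert transform_mrd(raw) == pytest.approx(expected)

    def test_negative_is_error(self):
        with pytest.raises(ValueError):
            transform_mrd(-0.1)

    @pytest.mark.parametrize(
        "raw,day,expected",
        [
            (0.5, 15, "0.01-<1%"),
            (5.0, 15, ">=5%"),
            (1.2, 42, ">=1%"),
            (0.005, 15, "<0.01%"),
            (0.01, 15, "0.01-<1%"),   # left-closed boundary
            (1.0, 15, "1-<5%"),
            (1.0, 42, ">=1%"),
        ],
    )
    def test_categories(self, raw, day, expected):
        assert categorize_mrd(raw, day) == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0.0, 50.0), st.sampled_from([15, 42]))
    def test_categorization_is_a_partition(self, raw, day):
        cats = DAY15_CATEGORIES if day == 15 else DAY42_CATEGORIES
        assert categorize_mrd(raw, day) in cats

    def test_longitudinal_groups_span_1_to_8(self):
        got = {assign_longitudinal_group(c, pos)
               for c in DAY15_CATEGORIES for pos in (False, True)}
        assert got == set(range(1, 9))

    @pytest.mark.parametrize(
        "cat15,pos42,expected",
        [("<0.01%", False, 1), (">=5%", True, 8), ("1-<5%", False, 5)],
    )
    def test_longitudinal_examples(self, cat15, pos42, expected):
        assert assign_longitudinal_group(cat15, pos42) == expected

    def test_measurement_record_consistency(self):
        m = MrdMeasurement("p1", day15_raw=2.0, day42_raw=0.004)
        assert m.day15_category == "1-<5%"
        assert m.day42_category == "<0.01%"
        assert m.day42_log10 == pytest.approx(math.log10(0.005))
        assert m.longitudinal_group == 5


class TestAnalysisTable:
    def test_small_matrix_with_one_missing_cell(self):
        est = pd.DataFrame({
            "patient_id": ["a", "a", "b", "b", "c"],
            "drug_id": ["prednisolone", "dasatinib"] * 2 + ["prednisolone"],
            "normalized_lc50": [0.1, 0.9, 0.5, 0.4, 0.3],
        })
        matrix, cov = build_analysis_table(est)
        assert matrix.shape == (3, 2)
        assert matrix.mask.to_numpy().sum() == 1
        assert matrix.n_observed == 5

    def test_duplicate_pairs_listed(self):
        est = pd.DataFrame({
            "patient_id": ["a", "a"],
            "drug_id": ["dasatinib", "dasatinib"],
            "normalized_lc50": [0.1, 0.2],
        })
        with pytest.raises(ValueError, match="dasatinib"):
            build_analysis_table(est)

    def test_empty_input_no_crash(self):
        matrix, cov = build_analysis_table(pd.DataFrame(
            columns=["patient_id", "drug_id", "normalized_lc50"]))
        assert matrix.shape[0] == 0

    def test_observed_values_validated(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            Lc50Matrix(pd.DataFrame({"dasatinib": [1.5]}, index=["a"]))


@pytest.mark.parametrize(
    "age,wbc,expected",
    [(5, 10, "standard"), (10, 10, "high"), (5, 50, "high"), (9.9, 49.9, "standard")],
)
def test_nci_risk(age, wbc, expected):
    assert nci_risk(age, wbc) == expected
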