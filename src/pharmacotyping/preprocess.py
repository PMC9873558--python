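"""Normalization of raw LC50 values, MRD transforms and table assembly.

Raw LC50 values are log10-transformed and min-max normalized per drug onto
[0, 1], where 0 is the most sensitive value attainable (the left-censor
bound, half the minimum tested concentration) and 1 the most resistant (the
right-censor bound, twice the maximum).  Minimal residual disease (MRD)
percentages are log10-transformed with below-detection values set to half
the detection limit, and binned into the clinical categories used for
day-15 (4 bins) and day-42 (3 bins) assessments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import DEFAULT_PANEL, DrugPanelSpec

__all__ = [
    "normalize_minmax",
    "denormalize_minmax",
    "normalize_fold_median",
    "transform_mrd",
    "categorize_mrd",
    "assign_longitudinal_group",
    "nci_risk",
    "Lc50Matrix",
    "build_analysis_table",
    "DAY15_CATEGORIES",
    "DAY42_CATEGORIES",
]

DAY15_CATEGORIES = ["<0.01%", "0.01-<1%", "1-<5%", ">=5%"]
DAY42_CATEGORIES = ["<0.01%", "0.01-<1%", ">=1%"]

#: The 23 molecular subtype labels of the cohort vocabulary.
SUBTYPES = [
    "ETV6-RUNX1", "Hyperdiploid", "T-ALL", "B-other", "PAX5alt", "DUX4",
    "KMT2A", "TCF3-PBX1", "BCR-ABL1", "CRLF2", "ETP", "ETV6-RUNX1-like",
    "BCR-ABL1-like", "iAMP21", "MEF2D", "Near-haploid", "ZNF384", "NUTM1",
    "PAX5 P80R", "Low-hypodiploid", "TCF3-HLF", "BCL2/MYC", "IKZF1 N159Y",
]


def nci_risk(age: float, wbc: float) -> str:
    """NCI risk group: standard iff age < 10 years and WBC < 50 x10^9/L."""
    return "standard" if (age < 10 and wbc < 50) else "high"


# ---------------------------------------------------------------------------
# LC50 normalization
# ---------------------------------------------------------------------------

def _log_bounds(panel: DrugPanelSpec, drug_id: str) -> tuple[float, float]:
    lo, hi = panel.censor_bounds(drug_id)
    return math.log10(lo), math.log10(hi)


def normalize_minmax(raw_lc50, panel: DrugPanelSpec = DEFAULT_PANEL, drug_id: str = ""):
    """Min-max normalize raw LC50 onto [0, 1] in log10 space.

    value = (log10(raw) - log10(min/2)) / (log10(2*max) - log10(min/2)).
    Left/right-censored values sit exactly at the bounds and map to exactly
    0 and 1.  Values outside [0, 1] after numeric noise are clamped with a
    warning.
    """
    llo, lhi = _log_bounds(panel, drug_id)
    raw = np.asarray(raw_lc50, dtype=float)
    with np.errstate(divide="ignore"):
        value = (np.log10(raw) - llo) / (lhi - llo)
    out_of_range = (value < -1e-9) | (value > 1 + 1e-9)
    if np.any(out_of_range & np.isfinite(value)):
        warnings.warn(f"{drug_id}: {int(np.sum(out_of_range))} raw LC50 value(s) "
                      "outside censor bounds; clamped to [0, 1]")
    value = np.clip(value, 0.0, 1.0)
    return float(value) if np.isscalar(raw_lc50) else value


def denormalize_minmax(value, panel: DrugPanelSpec = DEFAULT_PANEL, drug_id: str = ""):
    """Inverse of :func:`normalize_minmax` (exact in log space)."""
    llo, lhi = _log_bounds(panel, drug_id)
    value = np.asarray(value, dtype=float)
    raw = 10.0 ** (llo + value * (lhi - llo))
    return float(raw) if raw.ndim == 0 else raw


def normalize_fold_median(raw_lc50_vector):
    """Alternative per-drug normalization: log2 fold change from the median.

    The median is computed over measured (non-missing) values only.  Missing
    entries stay missing; an all-missing drug yields all-missing output with
    a warning.
    """
    raw = pd.Series(np.asarray(raw_lc50_vector, dtype=float))
    measured = raw.dropna()
    if measured.empty:
        warnings.warn("all values missing; fold-median normalization undefined")
        return raw.to_numpy()
    med = measured.median()
    if med <= 0:
        raise ValueError("median LC50 must be positive for fold-change normalization")
    return np.log2(raw.to_numpy() / med)


# ---------------------------------------------------------------------------
# MRD
# ---------------------------------------------------------------------------

def transform_mrd(raw_pct, detection_limit: float = 0.01) -> float:
    """log10 transform of an MRD percentage.

    Values below the detection limit (default 0.01%) are assigned half the
    detection limit before the log transform.
    """
    if raw_pct is None or (isinstance(raw_pct, float) and np.isnan(raw_pct)):
        return float("nan")
    if raw_pct < 0:
        raise ValueError(f"MRD must be non-negative, got {raw_pct}")
    if raw_pct < detection_limit:
        return math.log10(detection_limit / 2.0)
    return math.log10(raw_pct)


def categorize_mrd(raw_pct, day: int, detection_limit: float = 0.01) -> str:
    """Clinical MRD bin for day 15 (4 bins) or day 42 (3 bins).

    Day 15: <0.01%, >=0.01-<1%, >=1-<5%, >=5%.  Day 42: <0.01%, >=0.01-<1%,
    >=1%.  Boundaries are closed on the left as printed.
    """
    if raw_pct is None or (isinstance(raw_pct, float) and np.isnan(raw_pct)):
        return ""
    if raw_pct < 0:
        raise ValueError(f"MRD must be non-negative, got {raw_pct}")
    if day == 15:
        edges, cats = [detection_limit, 1.0, 5.0], DAY15_CATEGORIES
    elif day == 42:
        edges, cats = [detection_limit, 1.0], DAY42_CATEGORIES
    else:
        raise ValueError(f"day must be 15 or 42, got {day}")
    return cats[int(np.searchsorted(edges, raw_pct, side="right"))]


def assign_longitudinal_group(day15_category: str, day42_positive: bool) -> int | None:
    """Longitudinal induction-response group 1..8.

    Default mapping crosses the four day-15 categories with day-42
    positivity, ordered by increasing resistance: group 1 is day-15 <0.01%
    and day-42 negative; group 8 is day-15 >=5% and day-42 positive
    (``group = 2*day15_index + day42_positive + 1``).
    """
    if not day15_category or day42_positive is None:
        return None
    idx = DAY15_CATEGORIES.index(day15_category)
    return 2 * idx + int(bool(day42_positive)) + 1


@dataclass
class MrdMeasurement:
    """Day-15/day-42 MRD for one patient, with transforms and categories."""

    patient_id: str
    day15_raw: float | None
    day42_raw: float | None
    detection_limit: float = 0.01
    day15_log10: float = field(init=False)
    day42_log10: float = field(init=False)
    day15_category: str = field(init=False)
    day42_category: str = field(init=False)
    longitudinal_group: int | None = field(init=False)

    def __post_init__(self):
        self.day15_log10 = transform_mrd(self.day15_raw, self.detection_limit)
        self.day42_log10 = transform_mrd(self.day42_raw, self.detection_limit)
        self.day15_category = categorize_mrd(self.day15_raw, 15, self.detection_limit)
        self.day42_category = categorize_mrd(self.day42_raw, 42, self.detection_limit)
        if self.day15_category and self.day42_category:
            self.longitudinal_group = assign_longitudinal_group(
                self.day15_category, self.day42_raw >= self.detection_limit
            )
        else:
            self.longitudinal_group = None


# ---------------------------------------------------------------------------
# The central analysis object
# ---------------------------------------------------------------------------

class Lc50Matrix:
    """Patients x drugs matrix of normalized LC50 values with missingness.

    Thin wrapper over a pandas DataFrame (NaN marks missing) that fixes drug
    order and offers the missingness bookkeeping the pipeline logs.
    """

    def __init__(self, values: pd.DataFrame):
        values = values.astype(float)
        observed = values.to_numpy()
        finite = observed[np.isfinite(observed)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("observed normalized LC50 values must lie in [0, 1]")
        self.values = values

    @property
    def mask(self) -> pd.DataFrame:
        """True where the cell is missing."""
        return self.values.isna()

    @property
    def patient_ids(self) -> list:
        return list(self.values.index)

    @property
    def drug_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_observed(self) -> int:
        return int(self.values.notna().to_numpy().sum())

    def missingness_by_drug(self) -> pd.Series:
        return self.values.isna().mean(axis=0)

    def __eq__(self, other) -> bool:
        return isinstance(other, Lc50Matrix) and self.values.equals(other.values)


def build_analysis_table(
    lc50_estimates: pd.DataFrame,
    patients: pd.DataFrame | None = None,
    mrd: pd.DataFrame | None = None,
    panel: DrugPanelSpec = DEFAULT_PANEL,
    value_column: str = "normalized_lc50",
) -> tuple[Lc50Matrix, pd.DataFrame]:
    """Pivot long-format LC50 estimates into the analysis-ready matrix.

    ``lc50_estimates`` needs columns patient_id, drug_id and the value
    column.  Clinical covariates and MRD tables (indexed or keyed by
    patient_id) are aligned to the matrix rows.  Duplicate patient-drug
    pairs are an error listing the offenders.
    """
    if lc50_estimates.empty:
        return Lc50Matrix(pd.DataFrame(columns=panel.drug_ids, dtype=float)), pd.DataFrame()

    dup = lc50_estimates.duplicated(subset=["patient_id", "drug_id"], keep=False)
    if dup.any():
        offenders = lc50_estimates.loc[dup, ["patient_id", "drug_id"]].drop_duplicates()
        raise ValueError(f"duplicate patient-drug pairs:\n{offenders.to_string(index=False)}")
    unknown = set(lc50_estimates["drug_id"]) - set(panel.drug_ids)
    if unknown:
        raise ValueError(f"drug ids not in panel: {sorted(unknown)}")

    wide = lc50_estimates.pivot(index="patient_id", columns="drug_id", values=value_column)
    wide = wide.reindex(columns=[d for d in panel.drug_ids if d in wide.columns])
    matrix = Lc50Matrix(wide)

    cov = pd.DataFrame(index=wide.index)
    for extra in (patients, mrd):
        if extra is not None and not extra.empty:
            extra = extra.set_index("patient_id") if "patient_id" in extra.columns else extra
            cov = cov.join(extra, how="left")
    return matrix, cov
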