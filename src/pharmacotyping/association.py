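"""Drug-MRD and drug-covariate association statistics.

The central model is an ordinary least-squares regression of log10 MRD on
one drug's normalized LC50, adjusting for treatment protocol (categorical),
age and white-blood-cell count at diagnosis, fitted separately within B and
T lineages.  Because MRD is log10-transformed and LC50 is on a unit scale,
the coefficient beta has a direct fold-change reading: beta = 0.30
(log10(2)) means MRD is twice as high in the most resistant patients
(LC50 = 1) as in the most sensitive (LC50 = 0); beta = -0.30 means half.

Group contrasts of LC50 by clinical features use the Mann-Whitney U test
(two groups) or Kruskal-Wallis test (more), with Benjamini-Hochberg
correction across each drug family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

__all__ = [
    "AssociationResult",
    "GroupComparisonResult",
    "regress_lc50_on_mrd",
    "interpret_beta",
    "compare_groups",
    "trend_across_mrd_groups",
    "bh_adjust",
]


@dataclass
class AssociationResult:
    """One drug-MRD regression: beta is the change in log10 MRD per unit
    normalized LC50 (sensitive 0 -> resistant 1)."""

    drug_id: str
    timepoint: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    bh_adjusted_p: float = float("nan")
    flag: str = ""


@dataclass
class GroupComparisonResult:
    drug_id: str
    grouping: str
    test: str
    group_medians: dict
    group_sizes: dict
    statistic: float
    p: float
    bh_adjusted_p: float = float("nan")


def regress_lc50_on_mrd(
    lc50: pd.Series,
    mrd_log10: pd.Series,
    covariates: pd.DataFrame | None = None,
    drug_id: str = "",
    timepoint: str = "",
    min_n: int = 10,
    log_wbc: bool = True,
) -> AssociationResult:
    """OLS of log10 MRD on normalized LC50 with clinical adjustment.

    Covariate columns recognized: ``protocol`` (entered categorical,
    first-level reference), ``age`` (continuous years) and ``wbc``
    (continuous; log10-transformed by default).  Complete cases only.
    A constant LC50 column yields beta = NaN with a flag; a rank-deficient
    design raises an error naming the collinear columns.
    """
    drug_id = drug_id or (lc50.name if lc50.name else "")
    data = pd.DataFrame({"lc50": lc50, "mrd": mrd_log10})
    design_cols = ["lc50"]
    if covariates is not None and not covariates.empty:
        cov = covariates.copy()
        if "wbc" in cov.columns and log_wbc:
            cov["wbc"] = np.log10(cov["wbc"].astype(float))
        if "protocol" in cov.columns:
            dummies = pd.get_dummies(cov["protocol"].astype(str), prefix="protocol",
                                     drop_first=True, dtype=float)
            cov = pd.concat([cov.drop(columns=["protocol"]), dummies], axis=1)
        data = data.join(cov, how="inner")
        design_cols += [c for c in cov.columns]
    data = data.dropna()
    n = len(data)
    if n < min_n:
        return AssociationResult(drug_id, timepoint, np.nan, np.nan, np.nan,
                                 np.nan, np.nan, n, flag="insufficient_n")
    if data["lc50"].nunique() == 1:
        return AssociationResult(drug_id, timepoint, np.nan, np.nan, np.nan,
                                 np.nan, np.nan, n, flag="constant_predictor")

    X = sm.add_constant(data[design_cols].astype(float))
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # point at the columns whose removal restores full rank
        collinear = []
        for col in X.columns[1:]:
            if np.linalg.matrix_rank(X.drop(columns=[col]).to_numpy()) == rank:
                collinear.append(col)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    fit = sm.OLS(data["mrd"].astype(float), X).fit()
    ci = fit.conf_int().loc["lc50"]
    return AssociationResult(
        drug_id, timepoint,
        beta=float(fit.params["lc50"]), se=float(fit.bse["lc50"]),
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        p=float(fit.pvalues["lc50"]), n=n,
    )


def interpret_beta(beta: float) -> float:
    """Fold change in MRD between the most resistant (LC50 = 1) and most
    sensitive (LC50 = 0) patients implied by a regression coefficient:
    10**beta.  beta = 0.30 is about a twofold higher MRD; -0.30 about half."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return float(10.0 ** beta)


def compare_groups(
    values: pd.Series,
    groups: pd.Series,
    drug_id: str = "",
    grouping: str = "",
    min_group_size: int = 3,
    exact_max_n: int = 12,
) -> GroupComparisonResult:
    """Nonparametric LC50 contrast across clinical groups.

    Two groups: two-sided Mann-Whitney U (exact for combined n <= 12
    without ties, tie-corrected normal approximation otherwise).  More than
    two groups: Kruskal-Wallis.  Group medians are computed over measured
    values only.
    """
    drug_id = drug_id or (values.name if values.name else "")
    df = pd.DataFrame({"v": values, "g": groups}).dropna()
    arrays = {g: sub["v"].to_numpy() for g, sub in df.groupby("g", observed=True)}
    arrays = {g: a for g, a in arrays.items() if a.size >= min_group_size}
    if len(arrays) < 2:
        raise ValueError(f"{drug_id}/{grouping}: need >=2 groups with "
                         f">={min_group_size} measured values")
    medians = {g: float(np.median(a)) for g, a in arrays.items()}
    sizes = {g: int(a.size) for g, a in arrays.items()}
    samples = list(arrays.values())
    pooled = np.concatenate(samples)
    if np.unique(pooled).size == 1:
        warnings.warn(f"{drug_id}/{grouping}: all values tied; p = 1")
        test = "mannwhitneyu" if len(samples) == 2 else "kruskal"
        return GroupComparisonResult(drug_id, grouping, test, medians, sizes, 0.0, 1.0)
    if len(samples) == 2:
        a, b = samples
        method = "exact" if (a.size + b.size <= exact_max_n
                             and np.unique(pooled).size == pooled.size) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return GroupComparisonResult(drug_id, grouping, "mannwhitneyu", medians,
                                     sizes, float(res.statistic), float(res.pvalue))
    res = stats.kruskal(*samples)
    return GroupComparisonResult(drug_id, grouping, "kruskal", medians, sizes,
                                 float(res.statistic), float(res.pvalue))


def trend_across_mrd_groups(values: pd.Series, groups: pd.Series,
                            drug_id: str = "") -> GroupComparisonResult:
    """Kruskal-Wallis test of LC50 across the 8 longitudinal MRD groups.

    Group medians are returned for plotting; degenerate all-tied input
    yields p = 1 with a warning.
    """
    df = pd.DataFrame({"v": values, "g": groups}).dropna()
    arrays = {g: sub["v"].to_numpy() for g, sub in df.groupby("g", observed=True)
              if len(sub) > 0}
    if len(arrays) < 2:
        raise ValueError("need >=2 non-empty longitudinal groups")
    medians = {g: float(np.median(a)) for g, a in arrays.items()}
    sizes = {g: int(a.size) for g, a in arrays.items()}
    pooled = np.concatenate(list(arrays.values()))
    if np.unique(pooled).size == 1:
        warnings.warn("all values identical across MRD groups; p = 1")
        return GroupComparisonResult(drug_id, "longitudinal_mrd", "kruskal",
                                     medians, sizes, 0.0, 1.0)
    res = stats.kruskal(*arrays.values())
    return GroupComparisonResult(drug_id, "longitudinal_mrd", "kruskal", medians,
                                 sizes, float(res.statistic), float(res.pvalue))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values for one test family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
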