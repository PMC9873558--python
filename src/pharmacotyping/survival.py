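"""Event-free survival analysis of pharmacotype clusters.

EFS runs from diagnosis to the first treatment failure (induction failure,
relapse, second malignancy or death), censored at last contact.  Curves are
estimated per cluster (or per dasatinib-sensitivity group) with the
Kaplan-Meier product-limit estimator and Greenwood standard errors, groups
are compared with Mantel's log-rank test, and multivariable models use Cox
proportional-hazards regression with the treatment arm entered as
stratification (separate baseline hazards per arm) by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "KmCurve",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "dichotomize_dasatinib",
]


@dataclass
class KmCurve:
    group: object
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    greenwood_se: np.ndarray
    five_year: float
    five_year_se: float
    n: int = 0
    events: int = 0


def _validate_records(records: pd.DataFrame, time_col: str, event_col: str) -> None:
    t = records[time_col].to_numpy(dtype=float)
    e = records[event_col].to_numpy()
    if np.any(t <= 0) or np.any(~np.isfinite(t)):
        raise ValueError("EFS times must be positive and finite")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")


def km_estimate(
    records: pd.DataFrame,
    group_col: str | None = None,
    time_col: str = "efs_years",
    event_col: str = "event",
    horizon: float = 5.0,
) -> dict:
    """Kaplan-Meier curve per group with Greenwood variance.

    The ``horizon``-year survival (default 5) is read from the step
    function at exactly t = horizon.  Returns ``{group: KmCurve}`` (a
    single ``"all"`` entry when ``group_col`` is None).
    """
    _validate_records(records, time_col, event_col)
    if group_col is None:
        groups = {"all": records}
    else:
        groups = {g: sub for g, sub in records.groupby(group_col, observed=True)
                  if len(sub) > 0}
    out = {}
    for g, sub in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col])
        table = kmf.event_table
        surv_all = kmf.survival_function_["KM_estimate"]
        if table.index[0] == 0.0:       # lifelines' baseline row at t = 0
            table = table.iloc[1:]
            surv_all = surv_all.iloc[1:]
        at_risk = table["at_risk"].to_numpy(dtype=float)
        d = table["observed"].to_numpy(dtype=float)
        times = table.index.to_numpy(dtype=float)
        surv = surv_all.to_numpy()
        # Greenwood: var(S) = S^2 * cumsum(d / (n (n - d)))
        with np.errstate(divide="ignore", invalid="ignore"):
            inc = np.where(at_risk * (at_risk - d) > 0, d / (at_risk * (at_risk - d)), 0.0)
        se = surv * np.sqrt(np.cumsum(inc))
        step = np.searchsorted(times, horizon, side="right") - 1
        five_year = float(surv[step]) if step >= 0 else 1.0
        five_year_se = float(se[step]) if step >= 0 else 0.0
        out[g] = KmCurve(
            group=g, times=times, survival=surv, at_risk=at_risk,
            greenwood_se=se, five_year=five_year, five_year_se=five_year_se,
            n=len(sub), events=int(sub[event_col].sum()),
        )
    return out


def logrank_test(
    records: pd.DataFrame,
    group_col: str,
    time_col: str = "efs_years",
    event_col: str = "event",
) -> tuple[float, float]:
    """Mantel's log-rank chi-squared test across groups (g-1 df)."""
    _validate_records(records, time_col, event_col)
    if records[group_col].nunique() < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    if records[event_col].sum() == 0:
        warnings.warn("no events observed; log-rank p = 1")
        return 0.0, 1.0
    res = multivariate_logrank_test(records[time_col], records[group_col],
                                    records[event_col])
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    arm_col: str | None = "arm",
    arm_mode: str = "stratify",
    time_col: str = "efs_years",
    event_col: str = "event",
) -> pd.DataFrame:
    """Cox proportional-hazards fit with treatment-arm adjustment.

    The treatment arm enters as stratification by default (separate
    baseline hazards per arm), or as a categorical covariate with
    ``arm_mode="covariate"``.  Efron tie handling.  Returns a table with
    hazard ratios, 95% CIs and p-values per term; monotone likelihood /
    separation raises an informative error.
    """
    _validate_records(records, time_col, event_col)
    if records[event_col].sum() == 0:
        raise ValueError("Cox model needs at least one event")
    if not covariates:
        raise ValueError("no covariates to estimate")
    cols = [time_col, event_col] + list(covariates)
    df = records[cols + ([arm_col] if arm_col and arm_col in records.columns else [])].dropna()
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant; nothing to estimate")
    df = pd.get_dummies(df, columns=[c for c in covariates if df[c].dtype == object],
                        drop_first=True, dtype=float)
    fitter = CoxPHFitter()
    kwargs = {}
    if arm_col and arm_col in df.columns:
        if arm_mode == "stratify":
            kwargs["strata"] = [arm_col]
        else:
            df = pd.get_dummies(df, columns=[arm_col], drop_first=True, dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col=time_col, event_col=event_col, **kwargs)
    except ConvergenceError as err:
        raise ValueError(
            "Cox fit failed to converge (possible separation); consider "
            "grouping sparse categories or penalization"
        ) from err
    summary = fitter.summary
    out = pd.DataFrame({
        "hr": np.exp(summary["coef"]),
        "hr_ci_low": np.exp(summary["coef lower 95%"]),
        "hr_ci_high": np.exp(summary["coef upper 95%"]),
        "p": summary["p"],
        "coef": summary["coef"],
        "se": summary["se(coef)"],
    })
    out.index.name = "term"
    return out


def dichotomize_dasatinib(lc50, threshold: float = 0.25):
    """Dasatinib sensitivity groups: sensitive iff normalized LC50 < 0.25
    (strict); missing values stay unclassified."""
    scalar = np.isscalar(lc50)
    arr = pd.Series([lc50] if scalar else lc50, dtype=float)
    out = pd.Series(pd.NA, index=arr.index, dtype=object)
    out[arr < threshold] = "sensitive"
    out[arr >= threshold] = "resistant"
    return out.iloc[0] if scalar else out
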