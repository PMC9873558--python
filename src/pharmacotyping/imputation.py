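"""Sequential-regression (chained-equations) multiple imputation.

Missing cells of the normalized LC50 matrix are imputed by cycling through
the drug columns, regressing each on all others over its observed rows and
drawing imputations by predictive mean matching (PMM): a Bayesian linear
regression supplies predicted means, and each missing cell receives the
observed value of one of its five nearest donors in predicted-mean space.
Because draws come from observed donors, every imputed value stays inside
the observed [0, 1] range.  Ten completed datasets are produced by default.

Two validation procedures accompany the engine: a leave-one-out check that
masks each observed cell in turn and scores whether the observed value falls
inside the 95% interval of its ten imputations, and a per-drug chi-squared
comparison of imputed versus observed value distributions with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust

__all__ = [
    "ImputationSet",
    "LooValidationReport",
    "impute_chained",
    "loo_validate",
    "compare_distributions",
    "compare_coefficients",
]


@dataclass
class ImputationSet:
    """m completed copies of an LC50 matrix plus provenance."""

    datasets: list[pd.DataFrame]
    seed: int
    iterations: int
    method: str = "chained-pmm"

    @property
    def m(self) -> int:
        return len(self.datasets)

    def stacked(self) -> pd.DataFrame:
        """All m completed matrices stacked row-wise ((m*N) x D)."""
        return pd.concat(self.datasets, axis=0, keys=range(self.m),
                         names=["imputation", "patient_id"])

    def to_long(self) -> pd.DataFrame:
        frames = []
        for i, df in enumerate(self.datasets):
            long = df.stack().rename("value").reset_index()
            long.columns = ["patient_id", "drug_id", "value"]
            long.insert(2, "imputation", i)
            frames.append(long)
        return pd.concat(frames, ignore_index=True)


@dataclass
class LooValidationReport:
    cells: pd.DataFrame
    coverage: float
    m: int
    seed: int


# ---------------------------------------------------------------------------
# engine internals (plain ndarrays for speed)
# ---------------------------------------------------------------------------

def _chain_batch(values: np.ndarray, miss: np.ndarray, order: np.ndarray,
                 m: int, iterations: int, rng: np.random.Generator,
                 n_donors: int) -> np.ndarray:
    """Run m independent chains simultaneously; returns (m, n, p).

    ``values`` must arrive with missing cells pre-filled (column medians).
    Each column update draws regression coefficients from their posterior
    (normal draw around the least-squares solution with a scaled
    inverse-chi-squared variance) and matches predictions by PMM.  All
    linear algebra is batched over the chain axis; chains stay independent
    because every random draw carries a leading chain dimension.
    """
    n, p = values.shape
    X = np.broadcast_to(values, (m, n, p)).copy()
    ridge = np.eye(p) * 1e-8
    arange_p = np.arange(p)
    for _ in range(iterations):
        for j in order:
            mis = miss[:, j]
            obs = ~mis
            n_obs = int(obs.sum())
            n_mis = n - n_obs
            others = arange_p[arange_p != j]
            A = np.empty((m, n, p))
            A[:, :, 0] = 1.0
            A[:, :, 1:] = X[:, :, others]
            A_obs = A[:, obs, :]
            y = X[:, obs, j]                       # observed y, same per chain
            G = A_obs.transpose(0, 2, 1) @ A_obs + ridge
            rhs = np.einsum("mnp,mn->mp", A_obs, y)
            L = np.linalg.cholesky(G)
            beta_hat = np.linalg.solve(G, rhs[:, :, None])[:, :, 0]
            resid = y - np.einsum("mnp,mp->mn", A_obs, beta_hat)
            df = max(n_obs - p, 1)
            sigma2 = np.einsum("mn,mn->m", resid, resid) / rng.chisquare(df, m)
            # beta | sigma2 ~ N(beta_hat, sigma2 * G^{-1}); G = L L'
            z = rng.standard_normal((m, p))
            step = np.linalg.solve(L.transpose(0, 2, 1), z[:, :, None])[:, :, 0]
            beta_star = beta_hat + np.sqrt(sigma2)[:, None] * step
            yhat_obs = np.einsum("mnp,mp->mn", A_obs, beta_hat)
            yhat_mis = np.einsum("mnp,mp->mn", A[:, mis, :], beta_star)
            k = min(n_donors, n_obs)
            d = np.abs(yhat_mis[:, :, None] - yhat_obs[:, None, :])
            donor_idx = np.argpartition(d, k - 1, axis=2)[:, :, :k]
            pick = rng.integers(0, k, (m, n_mis))
            chosen = np.take_along_axis(donor_idx, pick[:, :, None], axis=2)[:, :, 0]
            X[:, mis, j] = np.take_along_axis(y, chosen, axis=1)
    return X


def _prepare(values: np.ndarray, min_obs: int, on_thin: str):
    """Column screening and median initialization; returns kept columns."""
    n, p = values.shape
    obs_counts = np.sum(~np.isnan(values), axis=0)
    thin = np.flatnonzero(obs_counts < min_obs)
    keep = np.flatnonzero(obs_counts >= min_obs)
    if thin.size:
        if on_thin == "error":
            raise ValueError(f"columns below observation threshold ({min_obs}): {thin.tolist()}")
        warnings.warn(f"excluding {thin.size} column(s) below observation threshold")
    if keep.size < 2:
        raise ValueError("imputation needs at least 2 usable columns")
    if np.any(np.all(np.isnan(values[:, keep]), axis=1)):
        raise ValueError("all-missing rows are not allowed")
    return keep


def impute_chained(
    matrix,
    m: int = 10,
    iterations: int = 10,
    seed: int = 0,
    n_donors: int = 5,
    on_thin_column: str = "warn",
    min_observed: int | None = None,
) -> ImputationSet:
    """Multiple imputation of an LC50 matrix by chained equations with PMM.

    Parameters
    ----------
    matrix : Lc50Matrix or DataFrame
        Patients x drugs values with NaN for missing cells.
    m : int
        Number of completed datasets (default 10).
    iterations : int
        Burn-in cycles through the columns per chain (default 10).
    seed : int
        Master seed; chains use independent spawned generators, so the
        result is bit-reproducible for a given (matrix, m, iterations, seed).
    n_donors : int
        PMM donor pool size (default 5).
    on_thin_column : {"warn", "error"}
        Policy for columns with fewer than ``min_observed`` observed values:
        exclude with a warning, or raise.
    min_observed : int, optional
        Observation threshold per column; defaults to max(10, 2*n_drugs),
        relaxed to max(10, n_drugs + 2) with a warning when the strict rule
        would leave fewer than two usable columns (tiny cohorts).

    Observed cells are never altered; columns are visited in order of
    descending missingness.
    """
    df = matrix.values if hasattr(matrix, "values") and not isinstance(matrix, pd.DataFrame) else matrix
    if not isinstance(df, pd.DataFrame):
        raise TypeError("matrix must be an Lc50Matrix or DataFrame")
    raw = df.to_numpy(dtype=float)
    n, p = raw.shape
    if p < 2:
        raise ValueError("imputation needs at least 2 columns")

    nan_mask = np.isnan(raw)
    if not nan_mask.any():
        return ImputationSet([df.copy() for _ in range(m)], seed, iterations)

    min_obs = min_observed
    if min_obs is None:
        min_obs = max(10, 2 * p)
        if (np.sum(~nan_mask, axis=0) >= min_obs).sum() < 2:
            relaxed = max(10, p + 2)
            warnings.warn(
                f"fewer than 2 columns reach {min_obs} observations; "
                f"relaxing threshold to {relaxed} for this small matrix")
            min_obs = relaxed
    keep = _prepare(raw, min_obs, on_thin_column)
    sub = raw[:, keep]
    miss = np.isnan(sub)
    medians = np.nanmedian(sub, axis=0)
    init = np.where(miss, medians[None, :], sub)
    order = np.argsort(-miss.mean(axis=0), kind="stable")
    order = order[miss[:, order].any(axis=0)]

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    batch = _chain_batch(init, miss, order, m, iterations, rng, n_donors)
    if not np.all(np.isfinite(batch)):
        bad = np.flatnonzero(~np.isfinite(batch).all(axis=(0, 1)))
        raise FloatingPointError(
            f"divergent chain: non-finite values in columns {bad.tolist()}")
    # excluded (thin) columns are dropped so every dataset is complete
    datasets = [pd.DataFrame(batch[i], index=df.index, columns=df.columns[keep])
                for i in range(m)]
    return ImputationSet(datasets, seed, iterations)


# ---------------------------------------------------------------------------
# validation procedures
# ---------------------------------------------------------------------------

def loo_validate(
    matrix,
    m: int = 10,
    seed: int = 0,
    iterations: int = 10,
    max_cells: int | None = None,
) -> LooValidationReport:
    """Leave-one-out validation of the imputation procedure.

    Each observed cell is masked in turn and the full chained-equations
    procedure is rerun (m imputations); the report records the mean and s.d.
    of the m imputed values and whether the held-out observation falls in
    the 95% interval ``mean +/- t(0.975, m-1) * sd``.  By default all
    observed cells are used when there are at most 5,000, otherwise a
    seeded random subsample of 2,000 cells.
    """
    df = matrix.values if hasattr(matrix, "values") and not isinstance(matrix, pd.DataFrame) else matrix
    raw = df.to_numpy(dtype=float)
    if raw.shape[1] < 2:
        raise ValueError("imputation needs at least 2 columns")
    obs_cells = np.argwhere(~np.isnan(raw))
    if obs_cells.shape[0] == 0:
        raise ValueError("matrix has no observed cells")

    # a cell that is its row's only observation cannot be held out: masking
    # it would leave an all-missing row, which the engine rejects
    row_obs = np.sum(~np.isnan(raw), axis=1)
    validatable = row_obs[obs_cells[:, 0]] > 1
    n_skipped = int((~validatable).sum())
    if n_skipped:
        warnings.warn(f"skipping {n_skipped} cell(s) that are their row's "
                      "only observation")
    obs_cells = obs_cells[validatable]
    if obs_cells.shape[0] == 0:
        raise ValueError("no validatable observed cells")

    rng = np.random.default_rng(seed)
    if max_cells is None:
        max_cells = obs_cells.shape[0] if obs_cells.shape[0] <= 5000 else 2000
    if max_cells > obs_cells.shape[0]:
        raise ValueError("subsample size exceeds observed cell count")
    if max_cells < obs_cells.shape[0]:
        sel = rng.choice(obs_cells.shape[0], size=max_cells, replace=False)
        obs_cells = obs_cells[sel]

    tcrit = stats.t.ppf(0.975, m - 1)
    rows = []
    for cell_no, (i, j) in enumerate(obs_cells):
        masked = df.copy()
        truth = float(raw[i, j])
        masked.iat[i, j] = np.nan
        imp = impute_chained(masked, m=m, iterations=iterations,
                             seed=int(rng.integers(0, 2**31 - 1)))
        vals = np.array([d.iat[i, j] for d in imp.datasets])
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        lo, hi = mean - tcrit * sd, mean + tcrit * sd
        rows.append((df.index[i], df.columns[j], truth, mean, sd, lo, hi,
                     bool(lo <= truth <= hi)))
    cells = pd.DataFrame(rows, columns=["patient_id", "drug_id", "observed",
                                        "imputed_mean", "imputed_sd",
                                        "ci_low", "ci_high", "covered"])
    return LooValidationReport(cells, float(cells["covered"].mean()), m, seed)


def _decile_bins(observed: np.ndarray) -> np.ndarray:
    """Interior decile edges; outer bins are open-ended."""
    return np.unique(np.quantile(observed, np.linspace(0.1, 0.9, 9)))


def _bin_counts(values: np.ndarray, inner_edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(inner_edges, values, side="right")
    return np.bincount(idx, minlength=inner_edges.size + 1)


def _merge_thin_bins(table: np.ndarray) -> np.ndarray:
    """Merge adjacent bins until every expected count is at least 5."""
    while table.shape[1] > 2:
        expected = stats.contingency.expected_freq(table)
        if expected.min() >= 5:
            break
        j = int(np.argmin(expected.min(axis=0)))
        k = j + 1 if j + 1 < table.shape[1] else j - 1
        table[:, min(j, k)] += table[:, max(j, k)]
        table = np.delete(table, max(j, k), axis=1)
    return table


def compare_distributions(observed: pd.DataFrame, imputation_set: ImputationSet) -> pd.DataFrame:
    """Chi-squared comparison of observed vs imputed value distributions.

    For each drug, the deciles of the observed values define bins; the
    imputed values (the cells that were missing, pooled across the m
    datasets) are binned identically and a two-sample chi-squared test is
    run on the 2 x bins contingency table.  p-values are BH-adjusted across
    the drug family.  Bins with expected counts below 5 are merged with a
    warning.
    """
    rows = []
    mask = observed.isna()
    imputed_cols = imputation_set.datasets[0].columns
    for drug in observed.columns:
        if drug not in imputed_cols:
            rows.append((drug, np.nan, np.nan, 0, 0))
            continue
        obs_vals = observed[drug].dropna().to_numpy()
        miss_rows = mask[drug].to_numpy()
        imp_vals = np.concatenate([
            d[drug].to_numpy()[miss_rows] for d in imputation_set.datasets
        ]) if miss_rows.any() else np.array([])
        if obs_vals.size < 2 or imp_vals.size < 2:
            rows.append((drug, np.nan, np.nan, obs_vals.size, imp_vals.size))
            continue
        edges = _decile_bins(obs_vals)
        c_obs = _bin_counts(obs_vals, edges)
        c_imp = _bin_counts(imp_vals, edges)
        table = np.vstack([c_obs, c_imp]).astype(float)
        table = table[:, table.sum(axis=0) > 0]
        merged = _merge_thin_bins(table.copy())
        if merged.shape[1] < table.shape[1]:
            warnings.warn(f"{drug}: merged thin bins for chi-squared comparison")
        if merged.shape[1] < 2:
            rows.append((drug, 0.0, 1.0, obs_vals.size, imp_vals.size))
            continue
        if np.array_equal(merged[0], merged[1]):
            rows.append((drug, 0.0, 1.0, obs_vals.size, imp_vals.size))
            continue
        chi2, p, _, _ = stats.chi2_contingency(merged)
        rows.append((drug, float(chi2), float(p), obs_vals.size, imp_vals.size))
    out = pd.DataFrame(rows, columns=["drug_id", "chi2", "p", "n_observed", "n_imputed"])
    valid = out["p"].notna()
    out["p_bh"] = np.nan
    if valid.any():
        out.loc[valid, "p_bh"] = bh_adjust(out.loc[valid, "p"].to_numpy())
    return out


def compare_coefficients(
    matrix,
    imputation_set: ImputationSet,
    mrd_log10: pd.Series,
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Compare MRD regression coefficients from measured vs imputed LC50.

    Per drug, beta is estimated from complete (measured) rows only and,
    separately, pooled across the m imputed datasets by Rubin's rules (the
    pooled point estimate is the mean of the per-imputation betas).  Returns
    the paired coefficients and their Pearson correlation, which is NaN when
    fewer than 3 valid pairs exist or either vector is constant.
    """
    from .association import regress_lc50_on_mrd

    df = matrix.values if hasattr(matrix, "values") and not isinstance(matrix, pd.DataFrame) else matrix
    rows = []
    imputed_cols = imputation_set.datasets[0].columns
    for drug in df.columns:
        measured = regress_lc50_on_mrd(df[drug], mrd_log10, covariates)
        if drug not in imputed_cols:
            rows.append((drug, measured.beta, np.nan))
            continue
        betas = [regress_lc50_on_mrd(d[drug], mrd_log10, covariates).beta
                 for d in imputation_set.datasets]
        betas = [b for b in betas if np.isfinite(b)]
        pooled = float(np.mean(betas)) if betas else np.nan
        rows.append((drug, measured.beta, pooled))
    out = pd.DataFrame(rows, columns=["drug_id", "beta_measured", "beta_imputed"])
    valid = out.dropna()
    if len(valid) < 3 or valid["beta_measured"].nunique() < 2 or valid["beta_imputed"].nunique() < 2:
        warnings.warn("coefficient correlation undefined (<3 pairs or zero variance)")
        return out, float("nan")
    r = float(np.corrcoef(valid["beta_measured"], valid["beta_imputed"])[0, 1])
    return out, r
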