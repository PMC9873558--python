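"""Consensus pharmacotype clustering over multiply imputed LC50 matrices.

The m completed matrices are stacked row-wise into an (m*N) x D matrix and
hierarchically clustered once with Manhattan (city-block) distances, so the
m replicate rows of every patient inherit labels from a single shared tree
and cluster indices are automatically comparable across imputations.  A
patient receives a final cluster only when the same label recurs in at
least 5 of the 10 replicates; a tie at the threshold leaves the patient
unassigned (conservative reading of the consensus rule).

Drug-side clustering uses a correlation distance (1 - Pearson r between
drug columns, pairwise-complete) for heatmap ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2_contingency

from .imputation import ImputationSet

__all__ = [
    "ConsensusClustering",
    "ClusterProfile",
    "stack_and_cluster",
    "consensus_assign",
    "cluster_drugs",
    "profile_clusters",
]

UNASSIGNED = 0


@dataclass
class ConsensusClustering:
    k: int
    replicate_labels: pd.DataFrame      # patients x m
    final_labels: pd.Series             # 0 = unassigned
    tie_flags: pd.Series
    linkage_matrix: np.ndarray = field(repr=False)
    threshold: int = 5

    @property
    def assigned_fraction(self) -> float:
        return float((self.final_labels != UNASSIGNED).mean())

    @property
    def n_unassigned(self) -> int:
        return int((self.final_labels == UNASSIGNED).sum())


@dataclass
class ClusterProfile:
    cluster: int
    n: int
    drug_medians: pd.Series
    subtype_fractions: pd.Series
    mrd15_fractions: pd.Series
    mrd42_fractions: pd.Series


def consensus_assign(labels, threshold: int = 5) -> tuple[int, bool]:
    """Final label from one patient's m replicate labels.

    Returns ``(label, tie)``; label is 0 (unassigned) when no cluster
    reaches the threshold, or when two clusters both reach it (tie).
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels)
    winners = np.flatnonzero(counts >= threshold)
    if winners.size == 1:
        return int(winners[0]), False
    return UNASSIGNED, winners.size > 1


def stack_and_cluster(
    imputations: ImputationSet,
    k: int = 6,
    linkage_method: str = "average",
    threshold: int = 5,
) -> ConsensusClustering:
    """Cluster the stacked imputed matrices and form consensus labels.

    All m completed matrices are concatenated ((m*N) x D), pairwise
    Manhattan distances are computed, and an agglomerative tree (average
    linkage by default; Ward is excluded as Euclidean-specific) is cut at
    ``k`` clusters.  Replicate labels are reshaped back per patient and the
    >= ``threshold`` of m consensus rule applied.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if linkage_method not in ("average", "complete"):
        raise ValueError("linkage_method must be 'average' or 'complete'")
    stacked = np.vstack([d.to_numpy(dtype=float) for d in imputations.datasets])
    if np.isnan(stacked).any():
        raise ValueError("imputed matrices must be complete (no NaN)")
    if k > np.unique(stacked, axis=0).shape[0]:
        raise ValueError("k exceeds the number of distinct rows")
    Z = linkage(pdist(stacked, metric="cityblock"), method=linkage_method)
    flat = fcluster(Z, t=k, criterion="maxclust")

    m = imputations.m
    index = imputations.datasets[0].index
    n = len(index)
    per_rep = flat.reshape(m, n).T           # patients x m
    replicate_labels = pd.DataFrame(per_rep, index=index,
                                    columns=[f"imp_{i}" for i in range(m)])
    finals, ties = zip(*(consensus_assign(row, threshold) for row in per_rep))
    return ConsensusClustering(
        k=k,
        replicate_labels=replicate_labels,
        final_labels=pd.Series(finals, index=index, name="cluster"),
        tie_flags=pd.Series(ties, index=index, name="tie"),
        linkage_matrix=Z,
        threshold=threshold,
    )


def cluster_drugs(lc50: pd.DataFrame, linkage_method: str = "average") -> np.ndarray:
    """Drug linkage tree from correlation distances (1 - Pearson r).

    Correlations are pairwise-complete over measured cells.  A drug column
    with zero variance makes its correlations undefined and is an error
    naming the drug.
    """
    if lc50.shape[1] < 3:
        raise ValueError("drug clustering needs >= 3 drugs")
    stds = lc50.std(ddof=0)
    flat = stds[stds == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance drug column(s): {flat}")
    corr = lc50.corr(method="pearson", min_periods=2)
    if corr.isna().any().any():
        bad = corr.columns[corr.isna().any()].tolist()
        raise ValueError(f"undefined correlation distance involving: {bad}")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    return linkage(squareform(dist, checks=False), method=linkage_method)


def profile_clusters(
    final_labels: pd.Series,
    lc50: pd.DataFrame,
    subtypes: pd.Series | None = None,
    mrd15_categories: pd.Series | None = None,
    mrd42_categories: pd.Series | None = None,
) -> tuple[list[ClusterProfile], dict]:
    """Per-cluster drug medians and composition fractions.

    Unassigned patients are excluded.  Returns the profiles plus
    chi-squared heterogeneity tests of subtype and MRD category
    composition across clusters (where those inputs are given).
    """
    assigned = final_labels[final_labels != UNASSIGNED]
    if assigned.empty:
        warnings.warn("no assigned patients; nothing to profile")
        return [], {}

    def _fractions(series: pd.Series | None, members) -> pd.Series:
        if series is None:
            return pd.Series(dtype=float)
        vals = series.reindex(members).dropna()
        vals = vals[vals.astype(str) != ""]
        if vals.empty:
            return pd.Series(dtype=float)
        return vals.value_counts(normalize=True).sort_index()

    profiles = []
    for c in sorted(assigned.unique()):
        members = assigned.index[assigned == c]
        profiles.append(ClusterProfile(
            cluster=int(c),
            n=len(members),
            drug_medians=lc50.reindex(members).median(axis=0),
            subtype_fractions=_fractions(subtypes, members),
            mrd15_fractions=_fractions(mrd15_categories, members),
            mrd42_fractions=_fractions(mrd42_categories, members),
        ))

    tests = {}
    for name, series in (("subtype", subtypes), ("mrd15", mrd15_categories),
                         ("mrd42", mrd42_categories)):
        if series is None:
            continue
        df = pd.DataFrame({"cluster": assigned, "cat": series.reindex(assigned.index)})
        df = df.dropna()
        df = df[df["cat"].astype(str) != ""]
        table = pd.crosstab(df["cluster"], df["cat"])
        if table.shape[0] > 1 and table.shape[1] > 1:
            chi2, p, _, _ = chi2_contingency(table)
            tests[name] = {"chi2": float(chi2), "p": float(p)}
    return profiles, tests
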