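"""End-to-end analysis driver: cohort -> imputation -> clusters -> MRD
association -> survival, with a machine-readable run manifest."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .association import (AssociationResult, bh_adjust, regress_lc50_on_mrd)
from .clustering import ConsensusClustering, cluster_drugs, profile_clusters, stack_and_cluster
from .imputation import ImputationSet, impute_chained
from .preprocess import Lc50Matrix
from .survival import cox_fit, dichotomize_dasatinib, km_estimate, logrank_test
from .synthetic import SimulationConfig, SyntheticCohort, simulate_cohort

log = logging.getLogger("pharmacotyping")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "render_reports"]


@dataclass
class PipelineConfig:
    """Resolved settings for one full run."""

    input_table: str | None = None            # wide LC50+clinical TSV; or None
    synthetic: SimulationConfig | None = None  # used when input_table is None
    seed: int = 0
    m: int = 10
    iterations: int = 10
    k: int = 6
    linkage: str = "average"
    threshold: int = 5
    dasatinib_cut: float = 0.25
    arm_mode: str = "stratify"
    outdir: str | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k != "synthetic"}
        d["synthetic"] = "default" if self.synthetic is None else "custom"
        return d


@dataclass
class PipelineResult:
    matrix: Lc50Matrix
    clinical: pd.DataFrame
    imputations: ImputationSet
    clustering: ConsensusClustering
    associations: pd.DataFrame
    km: dict
    logrank: tuple
    cox: pd.DataFrame | None
    manifest: dict
    cohort: SyntheticCohort | None = None
    profiles: list = field(default_factory=list)


def _associations_by_lineage(matrix, clinical, timepoint_col, timepoint,
                             lineage) -> list[AssociationResult]:
    rows = clinical[clinical["lineage"] == lineage]
    cov_cols = [c for c in ("protocol", "age", "wbc") if c in clinical.columns]
    results = []
    for drug in matrix.values.columns:
        res = regress_lc50_on_mrd(
            matrix.values.loc[matrix.values.index.intersection(rows.index), drug],
            rows[timepoint_col], rows[cov_cols], drug_id=drug, timepoint=timepoint,
        )
        results.append(res)
    ps = np.array([r.p for r in results])
    ok = np.isfinite(ps)
    if ok.any():
        adj = bh_adjust(ps[ok])
        for r, a in zip(np.array(results, dtype=object)[ok], adj):
            r.bh_adjusted_p = float(a)
    return results


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; stage failures abort naming the stage."""
    manifest: dict = {"seed": config.seed, "stages": []}
    cohort = None

    def stage(name):
        manifest["stages"].append(name)
        log.info("stage: %s", name)

    try:
        stage("cohort")
        if config.input_table:
            matrix, clinical = pio.read_lc50_table(config.input_table)
        else:
            cohort = simulate_cohort(config.synthetic or SimulationConfig(),
                                     seed=config.seed)
            matrix = Lc50Matrix(cohort.observed_lc50)
            clinical = cohort.clinical.join(cohort.mrd).join(
                cohort.survival.drop(columns=['arm']))
        manifest["n_patients"], manifest["n_drugs"] = matrix.shape
        manifest["n_observed_cells"] = matrix.n_observed
    except Exception:
        manifest["failed_stage"] = "cohort"
        raise

    try:
        stage("preprocess")
        manifest["missingness_by_drug"] = {
            k: round(float(v), 4) for k, v in matrix.missingness_by_drug().items()}
    except Exception:
        manifest["failed_stage"] = "preprocess"
        raise

    try:
        stage("imputation")
        imputations = impute_chained(matrix, m=config.m,
                                     iterations=config.iterations, seed=config.seed)
        manifest["m"] = imputations.m
        manifest["stacked_shape"] = list(imputations.stacked().shape)
    except Exception:
        manifest["failed_stage"] = "imputation"
        raise

    try:
        stage("clustering")
        clustering = stack_and_cluster(imputations, k=config.k,
                                       linkage_method=config.linkage,
                                       threshold=config.threshold)
        manifest["k"] = config.k
        manifest["n_unassigned"] = clustering.n_unassigned
        manifest["assigned_fraction"] = round(clustering.assigned_fraction, 4)
        profiles, heterogeneity = profile_clusters(
            clustering.final_labels, matrix.values,
            subtypes=clinical.get("subtype"),
            mrd15_categories=clinical.get("day15_category"),
            mrd42_categories=clinical.get("day42_category"))
        manifest["cluster_heterogeneity"] = heterogeneity
    except Exception:
        manifest["failed_stage"] = "clustering"
        raise

    try:
        stage("association")
        assoc_rows = []
        for lineage in ("B", "T"):
            for col, tp in (("day15_log10", "day15"), ("day42_log10", "day42")):
                if col not in clinical.columns:
                    continue
                for r in _associations_by_lineage(matrix, clinical, col, tp, lineage):
                    assoc_rows.append({"lineage": lineage, **r.__dict__})
        associations = pd.DataFrame(assoc_rows)
    except Exception:
        manifest["failed_stage"] = "association"
        raise

    try:
        stage("survival")
        surv_cols = {"efs_years", "event", "arm"}
        km = {}
        lr = (np.nan, np.nan)
        cox = None
        if surv_cols.issubset(clinical.columns):
            surv = clinical.dropna(subset=["efs_years", "event"]).copy()
            surv["cluster"] = clustering.final_labels.reindex(surv.index)
            surv = surv[surv["cluster"] != 0]
            surv["event"] = surv["event"].astype(int)
            km = km_estimate(surv, "cluster")
            lr = logrank_test(surv, "cluster")
            if "dasatinib" in matrix.values.columns:
                surv["dasatinib_group"] = dichotomize_dasatinib(
                    matrix.values["dasatinib"].reindex(surv.index),
                    config.dasatinib_cut)
            manifest["logrank_p"] = round(float(lr[1]), 6)
        else:
            warnings.warn("no survival columns present; survival stage skipped")
    except Exception:
        manifest["failed_stage"] = "survival"
        raise

    result = PipelineResult(matrix=matrix, clinical=clinical,
                            imputations=imputations, clustering=clustering,
                            associations=associations, km=km, logrank=lr,
                            cox=cox, manifest=manifest, cohort=cohort,
                            profiles=profiles)
    if config.outdir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    pio.write_lc50_matrix(result.matrix, out / "lc50_matrix.tsv")
    pio.write_imputation_set(result.imputations, out / "imputations.tsv")
    labels = result.clustering.replicate_labels.copy()
    labels["final"] = result.clustering.final_labels
    pio.write_table(labels, out / "cluster_labels.tsv")
    pio.write_table(result.associations, out / "associations.tsv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
    with open(out / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, default=str)


def render_reports(result: PipelineResult, outdir) -> list[Path]:
    """Figure files: subtype-by-drug median heatmap, beta forest plot,
    cluster heatmap of assigned patients, KM curves.  Missing upstream
    results skip the corresponding figure with a warning."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    values = result.matrix.values
    clinical = result.clinical

    if "subtype" in clinical.columns:
        med = values.join(clinical["subtype"]).groupby("subtype").median()
        fig, ax = plt.subplots(figsize=(10, 7))
        im = ax.imshow(med.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=0, vmax=1)
        ax.set_xticks(range(len(med.columns)), med.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(len(med.index)), med.index, fontsize=7)
        fig.colorbar(im, label="median normalized LC50")
        fig.tight_layout()
        p = out / "subtype_drug_medians.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        warnings.warn("no subtype column; skipping subtype heatmap")

    if not result.associations.empty:
        sub = result.associations.query("lineage == 'B' and timepoint == 'day15'")
        sub = sub.dropna(subset=["beta"])
        if not sub.empty:
            fig, ax = plt.subplots(figsize=(6, 6))
            y = np.arange(len(sub))
            sig = sub["bh_adjusted_p"] < 0.05
            colors = np.where(~sig, "black", np.where(sub["beta"] > 0, "red", "blue"))
            ax.hlines(y, sub["ci_low"], sub["ci_high"], color=colors)
            ax.scatter(sub["beta"], y, c=colors, zorder=3)
            ax.axvline(0, color="grey", lw=0.8)
            ax.set_yticks(y, sub["drug_id"], fontsize=7)
            ax.set_xlabel("beta (change in log10 MRD per unit LC50)")
            fig.tight_layout()
            p = out / "beta_forest_day15_B.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)

    assigned = result.clustering.final_labels
    assigned = assigned[assigned != 0].sort_values()
    if len(assigned):
        mean_imp = sum(d for d in result.imputations.datasets) / result.imputations.m
        block = mean_imp.reindex(assigned.index)
        fig, ax = plt.subplots(figsize=(10, 6))
        im = ax.imshow(block.to_numpy().T, aspect="auto", cmap="RdBu_r", vmin=0, vmax=1)
        ax.set_yticks(range(len(block.columns)), block.columns, fontsize=7)
        ax.set_xlabel("patients (assigned, ordered by cluster)")
        fig.colorbar(im, label="normalized LC50 (imputation mean)")
        fig.tight_layout()
        p = out / "cluster_heatmap.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    if result.km:
        fig, ax = plt.subplots(figsize=(6, 5))
        for g, curve in sorted(result.km.items(), key=lambda kv: str(kv[0])):
            ax.step(np.concatenate([[0], curve.times]),
                    np.concatenate([[1.0], curve.survival]),
                    where="post", label=f"cluster {g} (5y {curve.five_year:.2f})")
        ax.set_xlabel("years from diagnosis")
        ax.set_ylabel("EFS")
        ax.set_ylim(0, 1.02)
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = out / "km_clusters.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        warnings.warn("no KM curves; skipping survival figure")
    return written
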