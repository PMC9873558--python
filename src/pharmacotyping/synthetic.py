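"""Synthetic pharmacotyping cohort with exported ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: 805 patients spread over 23 molecular subtypes (frequencies from
the cohort's clinical characteristics table), each subtype mapped
probabilistically onto one of six drug-sensitivity archetypes; a patient's
true normalized LC50 profile is the archetype centroid plus Gaussian noise
clipped to [0, 1].  Cells are masked (MCAR by default) so that the expected
observed-cell count matches the 5,447 measured of 805 x 18 = 14,490
possible (about 62% missing).  log10 MRD is a linear function of the true
LC50 profile plus noise, floored at the 0.01% detection limit; event times
are exponential with proportional hazards by archetype, stratified by
treatment arm.  Every ground-truth layer (complete matrix, archetype
labels, beta vector, hazards) is exported so recovery tests never re-derive
the generative model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dose_response import four_pl
from .panel import DEFAULT_PANEL, DrugPanelSpec
from .preprocess import MrdMeasurement, denormalize_minmax, nci_risk

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_missingness",
    "simulate_mrd",
    "simulate_survival",
    "simulate_viability",
    "DEFAULT_ARCHETYPES",
]

DRUGS = DEFAULT_PANEL.drug_ids

#: Subtype counts of the 805-patient cohort (clinical characteristics table).
SUBTYPE_COUNTS = {
    "ETV6-RUNX1": 190, "Hyperdiploid": 178, "T-ALL": 113, "B-other": 59,
    "PAX5alt": 36, "DUX4": 34, "KMT2A": 32, "TCF3-PBX1": 30, "BCR-ABL1": 21,
    "CRLF2": 21, "ETP": 16, "ETV6-RUNX1-like": 14, "BCR-ABL1-like": 13,
    "iAMP21": 9, "MEF2D": 9, "Near-haploid": 8, "ZNF384": 8, "NUTM1": 5,
    "PAX5 P80R": 3, "Low-hypodiploid": 2, "TCF3-HLF": 2, "BCL2/MYC": 1,
    "IKZF1 N159Y": 1,
}

T_LINEAGE = {"T-ALL", "ETP"}

#: Six drug-sensitivity archetype centroids on the normalized [0, 1] scale.
#: 1: dasatinib/ibrutinib-sensitive; 2: venetoclax/trametinib-sensitive;
#: 3: asparaginase + glucocorticoid sensitive; 4: glucocorticoid-sensitive
#: but asparaginase-resistant; 5: pan-resistant to cytotoxics with residual
#: targeted-agent sensitivity; 6: glucocorticoid-resistant, mixed.
_ARCHETYPE_TABLE = {
    #                 1     2     3     4     5     6
    "asparaginase":  (0.57, 0.29, 0.02, 0.95, 0.85, 0.43),
    "bortezomib":    (0.70, 0.45, 0.30, 0.60, 0.90, 0.10),
    "chz868":        (0.05, 0.60, 0.85, 0.70, 0.45, 0.30),
    "cytarabine":    (0.55, 0.30, 0.10, 0.65, 0.95, 0.45),
    "dasatinib":     (0.02, 0.76, 0.95, 0.85, 0.52, 0.38),
    "daunorubicin":  (0.45, 0.30, 0.12, 0.80, 0.95, 0.60),
    "dexamethasone": (0.38, 0.21, 0.02, 0.12, 0.85, 0.95),
    "ibrutinib":     (0.05, 0.55, 0.80, 0.70, 0.25, 0.40),
    "mercaptopurine":(0.55, 0.35, 0.08, 0.20, 0.90, 0.70),
    "nelarabine":    (0.40, 0.55, 0.20, 0.75, 0.90, 0.65),
    "panobinostat":  (0.65, 0.25, 0.45, 0.55, 0.75, 0.10),
    "prednisolone":  (0.43, 0.29, 0.02, 0.12, 0.95, 0.85),
    "ruxolitinib":   (0.08, 0.70, 0.80, 0.60, 0.40, 0.50),
    "thioguanine":   (0.60, 0.30, 0.05, 0.40, 0.90, 0.70),
    "trametinib":    (0.45, 0.05, 0.80, 0.65, 0.15, 0.55),
    "venetoclax":    (0.75, 0.02, 0.40, 0.60, 0.22, 0.12),
    "vincristine":   (0.50, 0.35, 0.08, 0.75, 0.92, 0.60),
    "vorinostat":    (0.60, 0.40, 0.30, 0.50, 0.80, 0.15),
}

DEFAULT_ARCHETYPES = pd.DataFrame(
    {d: _ARCHETYPE_TABLE[d] for d in DRUGS}, index=[1, 2, 3, 4, 5, 6]
)

#: Probability of each subtype landing in each archetype, chosen to mirror
#: the qualitative cluster compositions (e.g. BCR-ABL1 and half of T-ALL in
#: the dasatinib-sensitive archetype; ETV6-RUNX1/hyperdiploid dominating the
#: chemosensitive ones; ETP and BCR-ABL1-like in the pan-resistant one).
SUBTYPE_ARCHETYPE_WEIGHTS = {
    #                      1     2     3     4     5     6
    "ETV6-RUNX1":       (0.00, 0.05, 0.75, 0.20, 0.00, 0.00),
    "Hyperdiploid":     (0.00, 0.35, 0.35, 0.25, 0.00, 0.05),
    "T-ALL":            (0.45, 0.00, 0.00, 0.00, 0.35, 0.20),
    "B-other":          (0.00, 0.15, 0.00, 0.40, 0.15, 0.30),
    "PAX5alt":          (0.00, 0.00, 0.00, 0.50, 0.20, 0.30),
    "DUX4":             (0.00, 0.00, 0.00, 0.80, 0.00, 0.20),
    "KMT2A":            (0.00, 0.00, 0.00, 0.35, 0.20, 0.45),
    "TCF3-PBX1":        (0.40, 0.00, 0.00, 0.40, 0.00, 0.20),
    "BCR-ABL1":         (0.75, 0.00, 0.00, 0.00, 0.00, 0.25),
    "CRLF2":            (0.00, 0.00, 0.00, 0.20, 0.30, 0.50),
    "ETP":              (0.00, 0.00, 0.00, 0.00, 0.70, 0.30),
    "ETV6-RUNX1-like":  (0.00, 0.30, 0.00, 0.50, 0.00, 0.20),
    "BCR-ABL1-like":    (0.00, 0.00, 0.00, 0.00, 0.50, 0.50),
    "iAMP21":           (0.00, 0.00, 0.00, 0.60, 0.00, 0.40),
    "MEF2D":            (0.00, 0.00, 0.00, 0.50, 0.00, 0.50),
    "Near-haploid":     (0.00, 0.40, 0.00, 0.00, 0.30, 0.30),
    "ZNF384":           (0.00, 0.50, 0.00, 0.00, 0.00, 0.50),
    "NUTM1":            (0.00, 0.00, 0.60, 0.40, 0.00, 0.00),
    "PAX5 P80R":        (0.00, 0.00, 0.00, 0.00, 0.60, 0.40),
    "Low-hypodiploid":  (0.00, 0.00, 0.00, 0.00, 0.50, 0.50),
    "TCF3-HLF":         (0.00, 0.00, 0.00, 0.00, 0.00, 1.00),
    "BCL2/MYC":         (0.00, 0.00, 0.00, 0.00, 0.00, 1.00),
    "IKZF1 N159Y":      (0.00, 0.00, 0.00, 0.00, 1.00, 0.00),
}

#: Day-15 MRD effect sizes (change in log10 MRD per unit normalized LC50)
#: for the drugs with reported associations; all others zero.
DEFAULT_BETA_DAY15 = {
    "asparaginase": 0.30, "prednisolone": 0.30, "dexamethasone": 0.28,
    "thioguanine": 0.18, "mercaptopurine": 0.17, "cytarabine": 0.15,
}


def _beta_series(betas) -> pd.Series:
    s = pd.Series(0.0, index=DRUGS)
    if betas:
        for k, v in betas.items():
            if k not in s.index:
                raise ValueError(f"beta for unknown drug {k!r}")
            s[k] = v
    return s


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_patients: int = 805
    panel: DrugPanelSpec = field(default_factory=lambda: DEFAULT_PANEL)
    subtype_counts: dict = field(default_factory=lambda: dict(SUBTYPE_COUNTS))
    archetypes: pd.DataFrame = field(default_factory=lambda: DEFAULT_ARCHETYPES.copy())
    archetype_weights: dict = field(
        default_factory=lambda: dict(SUBTYPE_ARCHETYPE_WEIGHTS))
    archetype_noise_sd: float = 0.08
    #: share of within-archetype variance carried by a per-patient, per-drug-
    #: class factor (same-class agents respond alike within a patient) and by
    #: a global per-patient resistance factor spanning all drugs
    noise_class_correlation: float = 0.3
    noise_global_correlation: float = 0.3
    # missingness: observed-cell probability matching 5,447 of 14,490 cells
    observed_rate: float = 5447.0 / 14490.0
    missingness_mechanism: str = "MCAR"          # or "drug-dependent"
    # MRD model
    beta_day15: dict = field(default_factory=lambda: dict(DEFAULT_BETA_DAY15))
    day42_attenuation: float = 0.7
    mrd_intercept_day15: float = -2.2
    mrd_intercept_day42: float = -3.2
    mrd_noise_sd: float = 0.9
    mrd_age_coef: float = 0.01
    mrd_logwbc_coef: float = 0.15
    detection_limit: float = 0.01
    # survival model
    baseline_hazard: dict = field(
        default_factory=lambda: {"LR": 0.015, "SHR": 0.035})
    cluster_log_hr: dict = field(
        default_factory=lambda: {1: np.log(2.8), 2: 0.35, 3: 0.0, 4: 0.10,
                                 5: np.log(2.3), 6: np.log(2.0)})
    followup_years: tuple = (4.0, 12.0)
    # viability layer
    viability_hill: float = 1.0
    viability_noise_sd: float = 0.02

    def __post_init__(self):
        for st, w in self.archetype_weights.items():
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(f"archetype weights for {st} must sum to 1")
        total = sum(self.subtype_counts.values())
        if total <= 0:
            raise ValueError("subtype counts must be positive")
        if not 0 <= self.observed_rate <= 1:
            raise ValueError("observed_rate must be in [0, 1]")
        if len(self.cluster_log_hr) != len(self.archetypes):
            raise ValueError("cluster_log_hr must cover every archetype")
        if any(h <= 0 for h in self.baseline_hazard.values()):
            raise ValueError("baseline hazards must be positive")

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticCohort:
    clinical: pd.DataFrame
    true_lc50: pd.DataFrame
    observed_lc50: pd.DataFrame
    true_clusters: pd.Series
    mrd: pd.DataFrame
    survival: pd.DataFrame
    true_beta_day15: pd.Series
    config: SimulationConfig
    seed: int


# ---------------------------------------------------------------------------

def _simulate_clinical(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_patients
    subtypes = list(cfg.subtype_counts)
    probs = np.array([cfg.subtype_counts[s] for s in subtypes], dtype=float)
    probs /= probs.sum()
    subtype = rng.choice(subtypes, size=n, p=probs)

    # age mixture: <1 yr (7/805), 1-<10 (603/805), >=10 (195/805)
    band = rng.choice(3, size=n, p=[7 / 805, 603 / 805, 195 / 805])
    age = np.where(band == 0, rng.uniform(0.3, 1.0, n),
                   np.where(band == 1, rng.uniform(1.0, 10.0, n),
                            rng.uniform(10.0, 19.0, n)))
    wbc = 10.0 ** rng.normal(1.3, 0.6, n)
    sex = rng.choice(["male", "female"], size=n, p=[440 / 805, 365 / 805])
    ancestry = rng.choice(
        ["European", "African", "Admixed American", "Other", "Unknown"],
        size=n, p=np.array([531, 104, 98, 65, 7]) / 805.0)
    protocol = rng.choice(["TotalXV", "TotalXVI", "TotalXVII"], size=n,
                          p=[0.3, 0.4, 0.3])
    risk = np.array([nci_risk(a, w) for a, w in zip(age, wbc)])
    arm = np.array([f"{p}-{'LR' if r == 'standard' else 'SHR'}"
                    for p, r in zip(protocol, risk)])
    lineage = np.where(np.isin(subtype, list(T_LINEAGE)), "T", "B")
    return pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "age": age, "wbc": wbc, "sex": sex, "ancestry": ancestry,
        "nci_risk": risk, "protocol": protocol, "arm": arm,
        "lineage": lineage, "subtype": subtype,
    }).set_index("patient_id")


def simulate_missingness(true_matrix: pd.DataFrame, cfg: SimulationConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Boolean mask (True = missing) under MCAR or drug-dependent rates.

    The drug-dependent mechanism spreads per-drug observed rates linearly
    between 0.6x and 1.4x the overall rate (capped at 1) while keeping the
    expected total observed-cell count at ``observed_rate * cells``.
    """
    n, p = true_matrix.shape
    if cfg.missingness_mechanism == "MCAR":
        rates = np.full(p, cfg.observed_rate)
    elif cfg.missingness_mechanism == "drug-dependent":
        scale = np.linspace(0.6, 1.4, p)
        rates = np.clip(cfg.observed_rate * scale, 0.0, 1.0)
        rates *= cfg.observed_rate * p / rates.sum()
        rates = np.clip(rates, 0.0, 1.0)
    else:
        raise ValueError(f"unknown missingness mechanism {cfg.missingness_mechanism!r}")
    observed = rng.random((n, p)) < rates[None, :]
    # every enrolled patient has at least one measurement (unless nothing
    # at all is observed by construction)
    if cfg.observed_rate > 0:
        empty = np.flatnonzero(~observed.any(axis=1))
        if empty.size:
            observed[empty, rng.integers(0, p, empty.size)] = True
    return pd.DataFrame(~observed, index=true_matrix.index,
                        columns=true_matrix.columns)


def simulate_mrd(true_lc50: pd.DataFrame, clinical: pd.DataFrame,
                 cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Day-15 and day-42 MRD from the linear log10 model.

    log10 MRD = intercept + sum_d beta_d * LC50_d + age/WBC terms + noise;
    the day-42 beta vector is the day-15 vector attenuated to mimic later
    clearance.  Values below the detection limit are flagged below-LOD and
    transformed from LOD/2.
    """
    beta15 = _beta_series(cfg.beta_day15).reindex(true_lc50.columns).fillna(0.0)
    beta42 = beta15 * cfg.day42_attenuation
    X = true_lc50.to_numpy()
    cov = (cfg.mrd_age_coef * (clinical["age"].to_numpy() - 7.0)
           + cfg.mrd_logwbc_coef * (np.log10(clinical["wbc"].to_numpy()) - 1.3))
    n = len(true_lc50)
    log15 = cfg.mrd_intercept_day15 + X @ beta15.to_numpy() + cov \
        + rng.normal(0, cfg.mrd_noise_sd, n)
    log42 = cfg.mrd_intercept_day42 + X @ beta42.to_numpy() + cov \
        + rng.normal(0, cfg.mrd_noise_sd, n)

    rows = []
    for pid, l15, l42 in zip(true_lc50.index, log15, log42):
        raw15 = min(10.0 ** l15, 100.0)
        raw42 = min(10.0 ** l42, 100.0)
        m = MrdMeasurement(pid, raw15, raw42, cfg.detection_limit)
        rows.append({
            "patient_id": pid,
            "day15_raw": raw15, "day42_raw": raw42,
            "day15_below_lod": raw15 < cfg.detection_limit,
            "day42_below_lod": raw42 < cfg.detection_limit,
            "day15_log10": m.day15_log10, "day42_log10": m.day42_log10,
            "day15_category": m.day15_category, "day42_category": m.day42_category,
            "longitudinal_group": m.longitudinal_group,
        })
    return pd.DataFrame(rows).set_index("patient_id")


def simulate_survival(cluster_labels: pd.Series, arms: pd.Series,
                      cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Exponential EFS times under proportional hazards by cluster.

    hazard = baseline(arm risk stratum) * exp(log HR of the patient's
    archetype); censoring is administrative at a uniform follow-up horizon.
    """
    n = len(cluster_labels)
    strata = np.array(["LR" if str(a).endswith("LR") else "SHR" for a in arms])
    base = np.array([cfg.baseline_hazard[s] for s in strata])
    loghr = np.array([cfg.cluster_log_hr[int(c)] for c in cluster_labels])
    hazard = base * np.exp(loghr)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(*cfg.followup_years, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({
        "patient_id": cluster_labels.index, "efs_years": time, "event": event,
        "arm": arms.to_numpy(),
    }).set_index("patient_id")


def simulate_viability(raw_lc50: float, grid_concentrations: np.ndarray,
                       rng: np.random.Generator, hill: float = 1.0,
                       noise_sd: float = 0.02) -> np.ndarray:
    """Forward 4PL viability curve (bottom 0, top 1, ec50 = raw LC50)."""
    x = np.log10(np.asarray(grid_concentrations, dtype=float))
    v = four_pl(x, 0.0, 1.0, hill, np.log10(raw_lc50))
    if noise_sd > 0:
        v = v + rng.normal(0, noise_sd, v.shape)
    return np.clip(v, 0.0, None)


def simulate_cohort(cfg: SimulationConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Draw a full synthetic cohort; identical (config, seed) gives an
    identical cohort bit for bit."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    clinical = _simulate_clinical(cfg, rng)

    weights = {s: np.asarray(w, dtype=float) for s, w in cfg.archetype_weights.items()}
    arch_ids = cfg.archetypes.index.to_numpy()
    clusters = np.array([
        rng.choice(arch_ids, p=weights[s]) for s in clinical["subtype"]
    ])
    centroids = cfg.archetypes.loc[clusters].to_numpy()
    if cfg.archetype_noise_sd > 0:
        # within-archetype variation: an independent per-cell part, a
        # per-patient per-drug-class factor (same-class drugs co-vary) and a
        # global per-patient ex vivo resistance factor spanning all drugs
        rho_c, rho_g = cfg.noise_class_correlation, cfg.noise_global_correlation
        if rho_c + rho_g > 1:
            raise ValueError("noise correlation shares must sum to <= 1")
        classes = [cfg.panel[d].drug_class for d in cfg.panel.drug_ids]
        class_ids = pd.factorize(pd.Series(classes))[0]
        eps = rng.standard_normal(centroids.shape)
        eta = rng.standard_normal((centroids.shape[0], class_ids.max() + 1))
        gamma = rng.standard_normal((centroids.shape[0], 1))
        noise = cfg.archetype_noise_sd * (
            np.sqrt(1.0 - rho_c - rho_g) * eps
            + np.sqrt(rho_c) * eta[:, class_ids]
            + np.sqrt(rho_g) * gamma)
    else:
        noise = 0.0
    true = np.clip(centroids + noise, 0.0, 1.0)
    true_lc50 = pd.DataFrame(true, index=clinical.index, columns=cfg.panel.drug_ids)
    true_clusters = pd.Series(clusters, index=clinical.index, name="true_cluster")

    mask = simulate_missingness(true_lc50, cfg, rng)
    observed = true_lc50.where(~mask)

    mrd = simulate_mrd(true_lc50, clinical, cfg, rng)
    surv = simulate_survival(true_clusters, clinical["arm"], cfg, rng)

    return SyntheticCohort(
        clinical=clinical, true_lc50=true_lc50, observed_lc50=observed,
        true_clusters=true_clusters, mrd=mrd, survival=surv,
        true_beta_day15=_beta_series(cfg.beta_day15), config=cfg, seed=seed,
    )
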