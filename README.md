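# pharmacotyping

Analysis pipeline for ex vivo drug-sensitivity profiling ("pharmacotyping")
of primary pediatric acute lymphoblastic leukemia (ALL) samples: from
six-point viability curves to censored LC50 estimates, normalized
drug-sensitivity matrices, multiply imputed consensus pharmacotype
clusters, minimal-residual-disease (MRD) association statistics and
event-free-survival (EFS) comparisons. It is written for biostatisticians
and computational biologists who want the full workflow — including the
imputation validity checks and the consensus rule — as tested, scriptable
components rather than a one-off analysis.

## The model in brief

For each sample and drug, viability fractions v at six concentrations c
are fitted with a four-parameter logistic in x = log10 c,

    v(x) = bottom + (top − bottom) / (1 + 10^(hill·(x − log10 EC50)))

and **LC50** is the concentration where the fitted curve crosses absolute
viability 0.5. If even the lowest dose kills >50% of cells, LC50 is
left-censored at min(c)/2; if >50% survive the highest dose it is
right-censored at 2·max(c). Raw LC50 values are log-transformed and
min-max normalized per drug onto [0, 1] (0 = most sensitive, 1 = most
resistant), with the censor bounds mapping exactly to 0 and 1.

Missing cells (~62% in the default cohort layout of 805 patients × 18
drugs) are completed by chained-equations multiple imputation with
predictive mean matching (m = 10). The ten completed matrices are stacked
(8,050 × 18), hierarchically clustered once with Manhattan distances, and
the tree is cut at k = 6; a patient joins a pharmacotype cluster only when
the same label recurs in ≥5 of 10 imputation replicates.

Drug–MRD association is ordinary least squares of log10 MRD on normalized
LC50 adjusting for protocol, age and WBC; a coefficient β means a 10^β
fold difference in MRD between the most resistant and most sensitive
patients (β = 0.30 ≈ twofold). Survival uses Kaplan–Meier curves with
Greenwood errors, Mantel's log-rank test and Cox proportional-hazards
models stratified by treatment arm.

A synthetic-cohort generator (`pharmacotyping.synthetic`) reproduces the
statistical structure of such a study — subtype frequencies, six planted
drug-sensitivity archetypes, calibrated missingness, a linear log-MRD
model and proportional-hazards EFS — and exports all ground truth, so
every stage has recovery tests against known answers.

## Worked example

Run the whole pipeline on the default synthetic cohort:

```bash
pharmacotyping run-all --n 805 --m 10 --k 6 --seed 1 --out runs/demo
```

which prints the run manifest (abridged):

```json
{
  "seed": 1,
  "stages": ["cohort", "preprocess", "imputation", "clustering",
             "association", "survival"],
  "n_patients": 805,
  "n_drugs": 18,
  "n_observed_cells": 5458,
  "m": 10,
  "stacked_shape": [8050, 18],
  "k": 6,
  "n_unassigned": 11,
  "assigned_fraction": 0.9863,
  "logrank_p": 0.0
}
```

Reading the numbers: 5,458 of 14,490 LC50 cells were measured (the
generator is calibrated to ~5,447); ten imputations stacked give the
8,050 × 18 clustering input; 11 of 805 patients had no cluster label
recurring in five of ten replicates and stay unassigned; and EFS differs
across the six pharmacotype clusters (the manifest rounds the log-rank p
to 6 decimals; the underlying value at this seed, as recomputed by
`scripts/acceptance.py`, is about 5e-8).

The same stages are available as library calls (`simulate_cohort`,
`impute_chained`, `stack_and_cluster`, `regress_lc50_on_mrd`,
`km_estimate`, `cox_fit`, …) and as separate CLI subcommands
(`simulate`, `lc50`, `normalize`, `impute`, `cluster`,
`validate-imputation`, `associate`, `survival`).

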