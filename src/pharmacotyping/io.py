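"""Readers and writers for the pipeline's tabular exchange formats.

All tables are UTF-8 TSV with a header row and '.' decimals.  The canonical
exchange layout for imputation sets is long format (patient, drug,
imputation, value); wide convenience exports exist but are lossy for
censor flags.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .imputation import ImputationSet
from .panel import DEFAULT_PANEL, DrugPanelSpec
from .preprocess import Lc50Matrix

__all__ = [
    "read_lc50_table",
    "write_lc50_matrix",
    "read_lc50_matrix",
    "write_imputation_set",
    "read_imputation_set",
    "read_viability_table",
    "write_table",
]

#: Clinical covariate columns recognized in an LC50 table.
CLINICAL_COLUMNS = [
    "age", "wbc", "sex", "ancestry", "nci_risk", "protocol", "arm",
    "lineage", "subtype", "day15_raw", "day42_raw", "day15_log10",
    "day42_log10", "day15_category", "day42_category", "longitudinal_group",
    "efs_years", "event",
]


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_lc50_matrix(matrix: Lc50Matrix | pd.DataFrame, path) -> None:
    df = matrix.values if isinstance(matrix, Lc50Matrix) else matrix
    write_table(df.rename_axis("patient_id"), path)


def read_lc50_matrix(path, panel: DrugPanelSpec = DEFAULT_PANEL) -> Lc50Matrix:
    df = pd.read_csv(path, sep="\t", index_col="patient_id")
    return _validate_matrix(df, panel)


def _validate_matrix(df: pd.DataFrame, panel: DrugPanelSpec) -> Lc50Matrix:
    unknown = [c for c in df.columns if c not in panel]
    if unknown:
        raise ValueError(f"columns not in drug panel: {unknown}")
    arr = df.to_numpy(dtype=float)
    bad = np.argwhere(np.isfinite(arr) & ((arr < 0) | (arr > 1)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"normalized LC50 out of [0, 1] at patient {df.index[i]!r}, "
            f"drug {df.columns[j]!r}: {arr[i, j]}"
        )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate patient ids: {dup}")
    return Lc50Matrix(df)


def read_lc50_table(
    path,
    panel: DrugPanelSpec = DEFAULT_PANEL,
    column_map: dict | None = None,
) -> tuple[Lc50Matrix, pd.DataFrame]:
    """Read a wide patient-level table mixing normalized LC50 and clinical
    columns (the layout of a supplementary-style patient dataset).

    Columns matching panel drug ids become the LC50 matrix; recognized
    clinical columns are returned alongside.  ``column_map`` renames input
    columns first (``{"file column": "canonical name"}``).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if column_map:
        df = df.rename(columns=column_map)
    if "patient_id" not in df.columns:
        raise ValueError("table needs a patient_id column")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient ids: {dup}")
    df = df.set_index("patient_id")
    drug_cols = [c for c in df.columns if c in panel]
    if not drug_cols:
        raise ValueError("no drug columns found matching the panel")
    matrix = _validate_matrix(df[drug_cols], panel)
    clinical = df[[c for c in df.columns if c not in panel]]
    return matrix, clinical


def read_viability_table(path) -> pd.DataFrame:
    """Long-format viability curves: sample_id, drug_id, concentration,
    viability plus optional assay_kind and QC columns."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"sample_id", "drug_id", "concentration", "viability"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"viability table missing columns: {sorted(missing)}")
    return df


def write_imputation_set(imp: ImputationSet, path) -> None:
    long = imp.to_long()
    long.attrs = {}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    header = {"m": imp.m, "seed": imp.seed, "iterations": imp.iterations,
              "method": imp.method}
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        long.to_csv(fh, sep="\t", index=False)


def read_imputation_set(path) -> ImputationSet:
    with open(path) as fh:
        header = json.loads(fh.readline().lstrip("# "))
        long = pd.read_csv(fh, sep="\t")
    datasets = []
    for i in range(header["m"]):
        sub = long[long["imputation"] == i]
        wide = sub.pivot(index="patient_id", columns="drug_id", values="value")
        datasets.append(wide)
    return ImputationSet(datasets, seed=header["seed"],
                         iterations=header["iterations"], method=header["method"])


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
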