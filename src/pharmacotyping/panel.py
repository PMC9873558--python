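"""Drug panel specification.

The default panel is the 18-agent ex vivo screening panel used for primary
ALL pharmacotyping: four antimetabolites, six non-antimetabolite cytotoxics,
five tyrosine-kinase inhibitors, two HDAC inhibitors and one BH3-mimetic.
Each drug is screened at six concentrations spanning the printed min-max
range; censored LC50 values are assigned at half the minimum tested
concentration (left) or twice the maximum (right), so those two bounds are
the extremes of the normalized [0, 1] sensitivity scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import yaml

ANTIMETABOLITE = "antimetabolite"
CYTOTOXIC = "non-antimetabolite cytotoxic"
TKI = "tyrosine kinase inhibitor"
HDAC = "HDAC inhibitor"
BH3 = "BH3-mimetic"


@dataclass(frozen=True)
class DrugInfo:
    """Concentration range and class of one panel drug."""

    drug_id: str
    min_conc: float
    max_conc: float
    units: str
    drug_class: str

    def __post_init__(self) -> None:
        if not (0 < self.min_conc < self.max_conc):
            raise ValueError(
                f"{self.drug_id}: need 0 < min_conc < max_conc, got "
                f"({self.min_conc}, {self.max_conc})"
            )

    @property
    def left_censor_value(self) -> float:
        """Raw LC50 assigned when even the lowest dose kills >50% of cells."""
        return self.min_conc / 2.0

    @property
    def right_censor_value(self) -> float:
        """Raw LC50 assigned when >50% of cells survive the highest dose."""
        return 2.0 * self.max_conc

    def default_grid(self) -> np.ndarray:
        """Six log-equispaced test concentrations between min and max."""
        return np.logspace(math.log10(self.min_conc), math.log10(self.max_conc), 6)


class DrugPanelSpec:
    """Ordered collection of :class:`DrugInfo` entries.

    Drug order is fixed at construction and defines the column order of every
    LC50 matrix downstream.
    """

    def __init__(self, drugs: list[DrugInfo]):
        if len({d.drug_id for d in drugs}) != len(drugs):
            raise ValueError("duplicate drug ids in panel")
        self._drugs = {d.drug_id: d for d in drugs}

    @property
    def drug_ids(self) -> list[str]:
        return list(self._drugs)

    def __len__(self) -> int:
        return len(self._drugs)

    def __iter__(self) -> Iterator[DrugInfo]:
        return iter(self._drugs.values())

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self._drugs

    def __getitem__(self, drug_id: str) -> DrugInfo:
        try:
            return self._drugs[drug_id]
        except KeyError:
            raise KeyError(f"unknown drug id: {drug_id!r}") from None

    def censor_bounds(self, drug_id: str) -> tuple[float, float]:
        d = self[drug_id]
        return d.left_censor_value, d.right_censor_value

    # ---- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            d.drug_id: {
                "min_conc": d.min_conc,
                "max_conc": d.max_conc,
                "units": d.units,
                "drug_class": d.drug_class,
            }
            for d in self
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DrugPanelSpec":
        return cls(
            [
                DrugInfo(drug_id=k, min_conc=v["min_conc"], max_conc=v["max_conc"],
                         units=v["units"], drug_class=v["drug_class"])
                for k, v in data.items()
            ]
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DrugPanelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: The 18-drug screening panel with printed tested-concentration ranges.
DEFAULT_PANEL = DrugPanelSpec(
    [
        DrugInfo("asparaginase", 0.032, 10.0, "IU/ml", CYTOTOXIC),
        DrugInfo("bortezomib", 0.98, 1000.0, "nM", CYTOTOXIC),
        DrugInfo("chz868", 0.1, 10000.0, "nM", TKI),
        DrugInfo("cytarabine", 0.04, 41.1, "uM", ANTIMETABOLITE),
        DrugInfo("dasatinib", 0.1, 10000.0, "nM", TKI),
        DrugInfo("daunorubicin", 0.004, 3.55, "uM", CYTOTOXIC),
        DrugInfo("dexamethasone", 0.00035, 11.6, "uM", CYTOTOXIC),
        DrugInfo("ibrutinib", 1.5625, 50.0, "uM", TKI),
        DrugInfo("mercaptopurine", 91.8, 2938.0, "uM", ANTIMETABOLITE),
        DrugInfo("nelarabine", 1.03, 250.0, "uM", ANTIMETABOLITE),
        DrugInfo("panobinostat", 0.98, 1000.0, "nM", HDAC),
        DrugInfo("prednisolone", 91.8, 2938.0, "uM", CYTOTOXIC),
        DrugInfo("ruxolitinib", 0.1, 10000.0, "nM", TKI),
        DrugInfo("thioguanine", 9.35, 299.0, "uM", ANTIMETABOLITE),
        DrugInfo("trametinib", 0.01, 1000.0, "nM", TKI),
        DrugInfo("venetoclax", 0.001, 100.0, "nM", BH3),
        DrugInfo("vincristine", 0.0017, 54.169, "uM", CYTOTOXIC),
        DrugInfo("vorinostat", 102.88, 25000.0, "nM", HDAC),
    ]
)
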