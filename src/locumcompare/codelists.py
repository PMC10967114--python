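"""Codelists: drug groups, condition groups, the ACSC ICD-10 registry and
multimorbidity weights.

Synthetic stand-in codelists ship with the package (``data/``); real Read/BNF
codelists can be supplied as delimited files with the same columns
(``code, description, group`` for drugs, ``code, description, condition`` for
conditions, ``icd10_prefix`` for the ACSC registry, ``condition, weight`` for
the multimorbidity weights).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError

#: drug groups every registry must be able to resolve
DRUG_GROUPS = (
    "antibiotic",
    "strong_opioid",
    "benzodiazepine",
    "z_drug",
    "nsaid",
    "ulcer_healing",
    "anticoagulant",
    "antiplatelet_nonaspirin",
    "aspirin",
    "nonselective_beta_blocker",
    "laba",
    "laba_ics_combo",
    "ics",
    "antipsychotic",
)


@dataclass(frozen=True)
class Codelist:
    """A named set of codes sharing one group tag."""

    name: str
    codes: frozenset
    group: str

    def __post_init__(self):
        if not self.codes:
            raise ConfigurationError(f"codelist {self.name!r} is empty")


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("locumcompare.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, dtype=str)


@dataclass
class CodelistRegistry:
    """Resolves drug codes to groups, clinical codes to conditions, ICD-10
    codes to ACSC membership, and conditions to multimorbidity weights."""

    drug_table: pd.DataFrame
    condition_table: pd.DataFrame
    acsc_prefixes: tuple
    cm_weights: dict = field(default_factory=dict)

    @classmethod
    def default(cls) -> "CodelistRegistry":
        return cls(
            drug_table=_read_packaged("codelists.csv"),
            condition_table=_read_packaged("conditions.csv"),
            acsc_prefixes=tuple(_read_packaged("acsc_icd10.csv")["icd10_prefix"]),
            cm_weights=_read_packaged("cm_weights.csv")
            .assign(weight=lambda d: d["weight"].astype(float))
            .set_index("condition")["weight"]
            .to_dict(),
        )

    @classmethod
    def from_files(cls, drug_path, condition_path, acsc_path, weights_path) -> "CodelistRegistry":
        drugs = pd.read_csv(drug_path, dtype=str)
        conds = pd.read_csv(condition_path, dtype=str)
        acsc = tuple(pd.read_csv(acsc_path, dtype=str)["icd10_prefix"])
        weights = (
            pd.read_csv(weights_path, dtype={"condition": str, "weight": float})
            .set_index("condition")["weight"]
            .to_dict()
        )
        return cls(drugs, conds, acsc, weights)

    # -- drug groups -----------------------------------------------------
    def drug_groups(self) -> set:
        return set(self.drug_table["group"].unique())

    def drug_codes(self, group: str) -> frozenset:
        """Codes of one drug group; ``hypnotic`` is the union of the
        benzodiazepine and z-drug lists."""
        if group == "hypnotic":
            return self.drug_codes("benzodiazepine") | self.drug_codes("z_drug")
        sub = self.drug_table.loc[self.drug_table["group"] == group, "code"]
        if sub.empty:
            raise ConfigurationError(f"unknown drug codelist group: {group!r}")
        return frozenset(sub)

    def drug_codelist(self, group: str) -> Codelist:
        return Codelist(name=group, codes=self.drug_codes(group), group=group)

    def code_to_group(self) -> dict:
        return self.drug_table.set_index("code")["group"].to_dict()

    # -- conditions ------------------------------------------------------
    def conditions(self) -> set:
        return set(self.condition_table["condition"].unique())

    def condition_codes(self, condition: str) -> frozenset:
        sub = self.condition_table.loc[
            self.condition_table["condition"] == condition, "code"
        ]
        if sub.empty:
            raise ConfigurationError(f"unknown condition group: {condition!r}")
        return frozenset(sub)

    def code_to_condition(self) -> dict:
        return self.condition_table.set_index("code")["condition"].to_dict()

    # -- ACSC ------------------------------------------------------------
    def is_acsc(self, icd10: pd.Series) -> pd.Series:
        """Whether each ICD-10 primary code falls in an ACSC chapter prefix."""
        codes = icd10.fillna("").astype(str)
        return codes.str.startswith(tuple(self.acsc_prefixes)) & (codes != "")

    # -- multimorbidity --------------------------------------------------
    def weight_for(self, condition: str) -> float:
        if condition not in self.cm_weights:
            raise ConfigurationError(
                f"no multimorbidity weight configured for condition {condition!r}"
            )
        return self.cm_weights[condition]
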