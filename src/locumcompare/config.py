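"""Generator and pipeline configuration: cohort structure and the ground-truth
generative model for consultation outcomes.

The defaults encode the study conditions of the source cohort: English
practices observed over financial years, ~10% of GP consultations staffed by
locums, outcome base rates matching the observed permanent-GP rates (revisit
8.2%, antibiotics 9.0%, ... same-day A&E 0.31%), and covariate distributions
with the observed means and spreads (age 46 (23.7), 55% female, multimorbidity
score 0.46, 16.4 years registered, list size 7,020 (3,493)).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError

#: the twelve consultation-level clinical-practice outcomes
OUTCOMES = (
    "revisit_7d",
    "rx_antibiotic",
    "rx_strong_opioid",
    "rx_hypnotic",
    "ae_same_day",
    "ae_1_7d",
    "emerg_same_day",
    "emerg_1_7d",
    "acsc_same_day",
    "acsc_1_7d",
    "referral",
    "test",
)

#: covariates entering the generative logistic model (standardised scales)
COVARIATE_NAMES = (
    "age",
    "female",
    "cm_score",
    "imd_quintile",
    "years_registered",
    "list_size",
    "year",
)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


# observed permanent-GP outcome rates used as default intercepts
_DEFAULT_RATES = {
    "revisit_7d": 0.0818,
    "rx_antibiotic": 0.0904,
    "rx_strong_opioid": 0.0226,
    "rx_hypnotic": 0.0086,
    "ae_same_day": 0.0031,
    "ae_1_7d": 0.0039,
    "emerg_same_day": 0.0016,
    "emerg_1_7d": 0.0015,
    "acsc_same_day": 0.0015,
    "acsc_1_7d": 0.0015,
    "referral": 0.0434,
    "test": 0.0321,
}

# default locum effects: log odds ratios of the observed locum-vs-permanent
# contrasts per outcome
_DEFAULT_LOCUM_OR = {
    "revisit_7d": 0.88,
    "rx_antibiotic": 1.21,
    "rx_strong_opioid": 1.08,
    "rx_hypnotic": 0.97,
    "ae_same_day": 1.02,
    "ae_1_7d": 1.05,
    "emerg_same_day": 0.94,
    "emerg_1_7d": 1.00,
    "acsc_same_day": 1.00,
    "acsc_1_7d": 0.99,
    "referral": 0.85,
    "test": 0.80,
}

_DEFAULT_COVARIATE_EFFECTS = {
    "age": 0.15,          # per 10 years above 45
    "female": 0.05,
    "cm_score": 0.20,     # per score point
    "imd_quintile": 0.05,  # per quintile above 3
    "years_registered": -0.02,  # per 10 years above 15
    "list_size": 0.0,     # per 3,500 patients above 7,000
    "year": 0.0,          # per financial year from the window midpoint
}

#: per-consultation probabilities of prescriptions unrelated to the twelve
#: outcomes; these populate the indicator engine's at-risk denominators
DEFAULT_BACKGROUND_RX = {
    "nsaid": 0.030,
    "ulcer_healing": 0.030,
    "anticoagulant": 0.010,
    "aspirin": 0.015,
    "antiplatelet_nonaspirin": 0.005,
    "nonselective_beta_blocker": 0.008,
    "laba": 0.004,
    "laba_ics_combo": 0.006,
    "ics": 0.015,
    "antipsychotic": 0.004,
}

#: lifetime prevalence of recorded condition flags
DEFAULT_CONDITION_PREVALENCE = {
    "asthma": 0.080,
    "peptic_ulcer": 0.010,
    "heart_failure": 0.012,
    "dementia": 0.012,
    "psychosis": 0.005,
    "diabetes": 0.060,
    "copd": 0.030,
    "hypertension": 0.140,
    "depression": 0.100,
    "epilepsy": 0.008,
    "ckd": 0.040,
    "atrial_fibrillation": 0.020,
    "coronary_heart_disease": 0.030,
}


@dataclass
class TruthTable:
    """Ground-truth generative parameters, retrievable for recovery tests.

    ``intercepts`` and ``locum_effects`` are per-outcome log-odds;
    ``covariate_effects`` are shared across outcomes and apply to the
    standardised covariates (see module docstring for scales).
    """

    intercepts: dict = field(default_factory=lambda: {
        k: _logit(v) for k, v in _DEFAULT_RATES.items()
    })
    locum_effects: dict = field(default_factory=lambda: {
        k: math.log(v) for k, v in _DEFAULT_LOCUM_OR.items()
    })
    covariate_effects: dict = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATE_EFFECTS)
    )

    def validate(self) -> None:
        for name, table in (
            ("intercepts", self.intercepts),
            ("locum_effects", self.locum_effects),
            ("covariate_effects", self.covariate_effects),
        ):
            for key, value in table.items():
                if not np.isfinite(value):
                    raise ConfigurationError(
                        f"non-finite truth value {name}[{key!r}] = {value!r}"
                    )
        unknown = set(self.intercepts) - set(OUTCOMES)
        unknown |= set(self.locum_effects) - set(OUTCOMES)
        if unknown:
            raise ConfigurationError(f"unknown outcome(s) in truth table: {sorted(unknown)}")
        unknown = set(self.covariate_effects) - set(COVARIATE_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown covariate(s) in truth table: {sorted(unknown)}")

    @classmethod
    def null(cls, outcomes=None, rates=None) -> "TruthTable":
        """Truth with no locum or covariate effects, restricted to ``outcomes``
        at the given base ``rates`` (defaults to the observed rates)."""
        outcomes = tuple(outcomes) if outcomes is not None else OUTCOMES
        rates = rates or {}
        return cls(
            intercepts={o: _logit(rates.get(o, _DEFAULT_RATES[o])) for o in outcomes},
            locum_effects={o: 0.0 for o in outcomes},
            covariate_effects={k: 0.0 for k in COVARIATE_NAMES},
        )


@dataclass
class CohortConfig:
    """Structure and rates of the synthetic cohort.

    ``locum_share`` is the probability that a GP-staffed consultation is with a
    locum; ``other_staff_share`` the share of consultations with non-GP staff.
    ``practice_sd``/``patient_sd`` are random-intercept SDs on the log-odds
    scale. ``locum_confounding`` optionally tilts locum exposure by the
    patient's multimorbidity score (log-odds per score point); the default 0
    keeps exposure ignorable.
    """

    n_regions: int = 3
    n_practices: int = 24
    patients_per_practice: int = 150
    study_start: pd.Timestamp = pd.Timestamp("2010-04-01")
    study_end: pd.Timestamp = pd.Timestamp("2013-03-31")
    consultation_rate: float = 4.0
    locum_share: float = 0.10
    other_staff_share: float = 0.20
    face_to_face_share: float = 0.80
    practice_sd: float = 0.15
    patient_sd: float = 0.30
    lookback_margin_days: int = 365
    locum_confounding: float = 0.0
    annual_death_rate: float = 0.008
    missing_age_gender_rate: float = 0.002
    background_rx: dict = field(default_factory=lambda: dict(DEFAULT_BACKGROUND_RX))
    condition_prevalence: dict = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_PREVALENCE)
    )
    seed: int = 0

    def __post_init__(self):
        self.study_start = pd.Timestamp(self.study_start)
        self.study_end = pd.Timestamp(self.study_end)

    def validate(self) -> None:
        if not (self.n_practices >= self.n_regions >= 1):
            raise ConfigurationError("need n_practices >= n_regions >= 1")
        if self.patients_per_practice < 0:
            raise ConfigurationError("patients_per_practice must be >= 0")
        if not self.study_start < self.study_end:
            raise ConfigurationError("study_start must precede study_end")
        for name in ("locum_share", "other_staff_share", "face_to_face_share"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        for name in ("practice_sd", "patient_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.consultation_rate < 0:
            raise ConfigurationError("consultation_rate must be >= 0")
        if self.lookback_margin_days < 0:
            raise ConfigurationError("lookback_margin_days must be >= 0")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=int(seed))


def standardise_covariates(frame: pd.DataFrame, mid_year: float) -> pd.DataFrame:
    """Map raw covariates to the standardised scales the truth table uses."""
    return pd.DataFrame(
        {
            "age": (frame["age"] - 45.0) / 10.0,
            "female": (frame["gender"] == "F").astype(float),
            "cm_score": frame["cm_score"].astype(float),
            "imd_quintile": frame["imd_quintile"].astype(float) - 3.0,
            "years_registered": (frame["years_registered"] - 15.0) / 10.0,
            "list_size": (frame["list_size"] - 7000.0) / 3500.0,
            "year": frame["fy_year"].astype(float) - mid_year,
        },
        index=frame.index,
    )


def load_config(path) -> tuple[CohortConfig, TruthTable, dict]:
    """Read a YAML pipeline configuration.

    Top-level keys: ``cohort`` (CohortConfig fields), ``truth`` (optional
    overrides of the default truth table: ``intercepts`` on the probability
    scale under key ``rates`` or log-odds under ``intercepts``,
    ``locum_odds_ratios`` or ``locum_effects``, ``covariate_effects``) and
    ``pipeline`` (free-form options passed through to the CLI).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_kwargs = dict(raw.get("cohort") or {})
    try:
        config = CohortConfig(**cohort_kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"bad cohort configuration: {exc}") from exc
    config.validate()

    truth = TruthTable()
    t = raw.get("truth") or {}
    if "rates" in t:
        truth.intercepts.update({k: _logit(float(v)) for k, v in t["rates"].items()})
    if "intercepts" in t:
        truth.intercepts.update({k: float(v) for k, v in t["intercepts"].items()})
    if "locum_odds_ratios" in t:
        truth.locum_effects.update(
            {k: math.log(float(v)) for k, v in t["locum_odds_ratios"].items()}
        )
    if "locum_effects" in t:
        truth.locum_effects.update({k: float(v) for k, v in t["locum_effects"].items()})
    if "covariate_effects" in t:
        truth.covariate_effects.update(
            {k: float(v) for k, v in t["covariate_effects"].items()}
        )
    truth.validate()
    return config, truth, dict(raw.get("pipeline") or {})
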