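"""Construction of the twelve binary clinical-practice outcomes and aligned
covariates for each sampled index consultation.

Window conventions (days are calendar-day differences, windows inclusive at
both ends): a practice revisit is any consultation of the same patient —
any staff role, any mode, including telephone and online — 1..7 days after
the index, so the index (or a second same-day consultation) never counts as
its own revisit. Hospital outcomes split into same-day (day 0) and days 1..7.
Prescription, test and referral outcomes are records linked to the index
consultation itself.
"""
from __future__ import annotations

import logging
import warnings
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .bundle import EHRBundle
from .codelists import Codelist, CodelistRegistry
from .errors import ConfigurationError, IntegrityError
from .periods import fy_start_year

log = logging.getLogger(__name__)

OUTCOME_COLUMNS = [
    "revisit_7d", "rx_antibiotic", "rx_strong_opioid", "rx_hypnotic",
    "ae_same_day", "ae_1_7d", "emerg_same_day", "emerg_1_7d",
    "acsc_same_day", "acsc_1_7d", "referral", "test",
]

COVARIATE_COLUMNS = [
    "age", "gender", "cm_score", "years_registered",
    "imd_quintile", "list_size", "rurality",
]


def round_half_up(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, ROUND_HALF_UP))


def _index_frame(bundle: EHRBundle, index) -> pd.DataFrame:
    """Normalise an index set (ids or audit frame) to consultation rows."""
    cons = bundle.consultations.set_index("consultation_id")
    if isinstance(index, pd.DataFrame):
        ids = index["consultation_id"]
    else:
        ids = pd.Series(list(index))
    missing = ~ids.isin(cons.index)
    if missing.any():
        raise IntegrityError(f"{int(missing.sum())} index consultation(s) not in bundle")
    rows = cons.loc[ids]
    return pd.DataFrame(
        {
            "consultation_id": ids.to_numpy(),
            "patient_id": rows["patient_id"].to_numpy(),
            "date": rows["date"].to_numpy(),
            "staff_role": rows["staff_role"].to_numpy(),
        }
    )


def _window_any(index_df: pd.DataFrame, events: pd.DataFrame,
                lo: int, hi: int) -> pd.Series:
    """1 iff the patient has an event dated lo..hi days after the index."""
    if index_df.empty or events.empty:
        return pd.Series(np.zeros(len(index_df), dtype=np.int8), index=index_df.index)
    merged = index_df[["consultation_id", "patient_id", "date"]].merge(
        events, on="patient_id", how="inner", suffixes=("", "_ev")
    )
    delta = (merged["date_ev"] - merged["date"]).dt.days
    merged["hit"] = (delta >= lo) & (delta <= hi)
    hits = merged.groupby("consultation_id")["hit"].any()
    out = index_df["consultation_id"].map(hits).eq(True)
    return out.astype(np.int8)


def flag_revisit(bundle: EHRBundle, index, window_days: int = 7) -> pd.Series:
    """Any further consultation 1..window_days days after the index."""
    index_df = _index_frame(bundle, index)
    events = bundle.consultations[["patient_id", "date"]].rename(
        columns={"date": "date_ev"}
    )
    if index_df.empty or events.empty:
        return pd.Series(np.zeros(len(index_df), dtype=np.int8))
    merged = index_df.merge(events, on="patient_id", how="inner")
    delta = (merged["date_ev"] - merged["date"]).dt.days
    merged["hit"] = (delta >= 1) & (delta <= window_days)
    hits = merged.groupby("consultation_id")["hit"].any()
    return index_df["consultation_id"].map(hits).eq(True).astype(np.int8)


def flag_prescription(bundle: EHRBundle, index, codelist: Codelist) -> pd.Series:
    """A therapy record with a code in the codelist linked to the index."""
    index_df = _index_frame(bundle, index)
    with_rx = set(bundle.therapy.loc[
        bundle.therapy["drug_code"].isin(codelist.codes), "consultation_id"
    ])
    return index_df["consultation_id"].isin(with_rx).astype(np.int8)


def flag_hospital(bundle: EHRBundle, index, kind: str,
                  registry: CodelistRegistry | None = None):
    """Same-day and 1..7-day flags for one hospital outcome.

    ``kind`` is ``ae_visit``, ``emergency_admission`` or ``acsc_admission``;
    ACSC admissions are emergency admissions whose primary ICD-10 code falls
    in the configured ACSC chapter set (malformed/missing codes are skipped
    with a warning)."""
    index_df = _index_frame(bundle, index)
    hosp = bundle.hospital
    if kind == "acsc_admission":
        registry = registry or CodelistRegistry.default()
        adm = hosp[hosp["kind"] == "emergency_admission"]
        codes = adm["icd10"].fillna("").astype(str)
        malformed = codes == ""
        if malformed.any():
            warnings.warn(
                f"{int(malformed.sum())} emergency admission(s) without a parsable "
                "primary ICD-10 code skipped in ACSC matching"
            )
        events = adm[registry.is_acsc(adm["icd10"])]
    elif kind in ("ae_visit", "emergency_admission"):
        events = hosp[hosp["kind"] == kind]
    else:
        raise ConfigurationError(f"unknown hospital outcome kind {kind!r}")
    events = events[["patient_id", "date"]].rename(columns={"date": "date_ev"})
    same_day = _window_any(index_df, events, 0, 0)
    within_1_7 = _window_any(index_df, events, 1, 7)
    return same_day, within_1_7


def _flag_event(bundle: EHRBundle, index, kind: str) -> pd.Series:
    index_df = _index_frame(bundle, index)
    linked = set(bundle.consult_events.loc[
        bundle.consult_events["kind"] == kind, "consultation_id"
    ])
    return index_df["consultation_id"].isin(linked).astype(np.int8)


def flag_test(bundle: EHRBundle, index) -> pd.Series:
    """A test order linked to the index consultation."""
    return _flag_event(bundle, index, "test")


def flag_referral(bundle: EHRBundle, index) -> pd.Series:
    """A referral to any other service made at the index consultation."""
    return _flag_event(bundle, index, "referral")


def compute_multimorbidity(bundle: EHRBundle,
                           registry: CodelistRegistry | None = None,
                           baseline_end=None) -> pd.Series:
    """Weighted multimorbidity score per patient, from condition flags
    recorded on or before the end of the baseline year. The score is fixed
    at baseline for all study years."""
    registry = registry or CodelistRegistry.default()
    if baseline_end is None:
        window = bundle.meta.get("window", {})
        start = pd.Timestamp(window.get("start", bundle.consultations["date"].min()))
        baseline_end = pd.Timestamp(year=start.year, month=12, day=31)
    baseline_end = pd.Timestamp(baseline_end)

    score = pd.Series(0.0, index=bundle.patients["patient_id"])
    clin = bundle.clinical[bundle.clinical["date"] <= baseline_end]
    code_cond = registry.code_to_condition()
    conds = clin["condition_code"].map(code_cond)
    for cond, grp in clin.groupby(conds):
        weight = registry.weight_for(cond)
        score.loc[score.index.isin(set(grp["patient_id"]))] += weight
    return score


def attach_covariates(bundle: EHRBundle, frame: pd.DataFrame,
                      registry: CodelistRegistry | None = None,
                      baseline_end=None) -> pd.DataFrame:
    """Add index-date-aligned covariates and cluster labels to any frame with
    ``patient_id`` and ``date`` columns (plus ``fy``/``fy_year`` if absent)."""
    registry = registry or CodelistRegistry.default()
    table = frame.copy()
    if "fy_year" not in table.columns:
        table["fy_year"] = fy_start_year(table["date"]) if len(table) else []
    if "fy" not in table.columns:
        table["fy"] = [f"{y}-{y + 1}" for y in table["fy_year"]]
    pts = bundle.patients.set_index("patient_id")
    prax = bundle.practices.set_index("practice_id")
    table["practice_id"] = table["patient_id"].map(pts["practice_id"])
    table["region"] = table["patient_id"].map(pts["region"])
    table["gender"] = table["patient_id"].map(pts["gender"])
    table["age"] = table["fy_year"] - table["patient_id"].map(pts["birth_year"])
    table["imd_quintile"] = table["patient_id"].map(pts["imd_quintile"])
    reg_start = table["patient_id"].map(pts["reg_start"])
    table["years_registered"] = (table["date"] - reg_start).dt.days / 365.25
    cm = compute_multimorbidity(bundle, registry, baseline_end)
    table["cm_score"] = table["patient_id"].map(cm)
    table["list_size"] = table["practice_id"].map(prax["list_size"])
    table["rurality"] = table["practice_id"].map(prax["rurality"])
    return table


def build_outcome_table(bundle: EHRBundle, index,
                        registry: CodelistRegistry | None = None,
                        baseline_end=None) -> pd.DataFrame:
    """One row per index consultation: exposure (locum=1), the twelve binary
    outcomes, and covariates aligned to the index date. Age is the financial
    year's start year minus birth year; years registered is the time from
    registration start to the index date."""
    registry = registry or CodelistRegistry.default()
    index_df = _index_frame(bundle, index)
    if isinstance(index, pd.DataFrame) and "fy" in index.columns:
        fy_label = index["fy"].to_numpy()
    else:
        years = fy_start_year(index_df["date"])
        fy_label = np.array([f"{y}-{y + 1}" for y in years])

    table = index_df[["consultation_id", "patient_id", "date"]].copy()
    table["locum"] = (index_df["staff_role"] == "locum_gp").astype(np.int8)
    table["fy"] = fy_label
    table["fy_year"] = fy_start_year(index_df["date"])

    table["revisit_7d"] = flag_revisit(bundle, index_df).to_numpy()
    table["rx_antibiotic"] = flag_prescription(
        bundle, index_df, registry.drug_codelist("antibiotic")).to_numpy()
    table["rx_strong_opioid"] = flag_prescription(
        bundle, index_df, registry.drug_codelist("strong_opioid")).to_numpy()
    table["rx_hypnotic"] = flag_prescription(
        bundle, index_df, registry.drug_codelist("hypnotic")).to_numpy()
    for kind, prefix in (("ae_visit", "ae"), ("emergency_admission", "emerg"),
                         ("acsc_admission", "acsc")):
        same, later = flag_hospital(bundle, index_df, kind, registry)
        table[f"{prefix}_same_day"] = same.to_numpy()
        table[f"{prefix}_1_7d"] = later.to_numpy()
    table["referral"] = flag_referral(bundle, index_df).to_numpy()
    table["test"] = flag_test(bundle, index_df).to_numpy()

    table = attach_covariates(bundle, table, registry, baseline_end)

    cols = (["consultation_id", "patient_id", "practice_id", "region", "fy",
             "fy_year", "date", "locum"] + OUTCOME_COLUMNS + COVARIATE_COLUMNS)
    return table[cols]


def summarize_outcomes(table: pd.DataFrame) -> pd.DataFrame:
    """Descriptive summary in the shape of the published Table 1: per-role
    outcome counts with percentages (two decimals, round half-up), and
    means/SDs of patient and practice characteristics."""
    rows = []
    for role, locum in (("permanent_gp", 0), ("locum_gp", 1)):
        sub = table[table["locum"] == locum]
        n = len(sub)
        for outcome in OUTCOME_COLUMNS:
            count = int(sub[outcome].sum()) if n else 0
            pct = round_half_up(100.0 * count / n, 2) if n else None
            rows.append({"role": role, "measure": outcome, "kind": "outcome",
                         "n": n, "count": count, "value": pct,
                         "display": f"{count:,}({pct:.2f}%)" if n else ""})
        numeric = {
            "cm_score": sub["cm_score"], "age": sub["age"],
            "female": (sub["gender"] == "F").astype(float),
            "years_registered": sub["years_registered"],
            "imd_quintile": sub["imd_quintile"].astype(float),
            "rurality": sub["rurality"].astype(float),
            "list_size": sub["list_size"].astype(float),
        }
        for name, series in numeric.items():
            mean = float(series.mean()) if n else None
            sd = float(series.std()) if n else None
            rows.append({"role": role, "measure": name, "kind": "characteristic",
                         "n": n, "count": None, "value": mean,
                         "display": f"{mean:.2f} ({sd:.2f})" if n else ""})
    return pd.DataFrame(rows)
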