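"""Eligibility rules and construction of the analysis consultation sets.

Two designs are served: one random face-to-face GP consultation per patient
per financial year (clinical-practice outcomes), and all face-to-face GP
consultations satisfying an indicator's index predicate (prescribing-safety
indicators, repeated consultations per patient retained).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bundle import EHRBundle, GP_ROLES
from .periods import FinancialYear, financial_years

log = logging.getLogger(__name__)


@dataclass
class EligibilityRules:
    """Cohort eligibility. Patients whose recorded *year* of death precedes
    the study start year are excluded outright (year granularity); individual
    consultations after the recorded death *date* are dropped; consultations
    of patients missing age or gender are dropped."""

    study_start: pd.Timestamp
    require_alive_at_start: bool = True
    drop_post_death_consultations: bool = True
    require_age_gender: bool = True

    def __post_init__(self):
        self.study_start = pd.Timestamp(self.study_start)


def filter_eligible(bundle: EHRBundle, rules: EligibilityRules) -> EHRBundle:
    """Apply eligibility rules; removal counts land in ``meta['exclusions']``
    and the log. Idempotent."""
    out = bundle.copy()
    counts = {}

    if rules.require_alive_at_start:
        death_year = out.patients["death_date"].dt.year
        dead_before = death_year.notna() & (death_year < rules.study_start.year)
        counts["patients_dead_before_study"] = int(dead_before.sum())
        keep = set(out.patients.loc[~dead_before, "patient_id"])
        out.patients = out.patients[~dead_before].reset_index(drop=True)
        for name in ("consultations", "clinical", "hospital"):
            frame = getattr(out, name)
            setattr(out, name, frame[frame["patient_id"].isin(keep)].reset_index(drop=True))

    if rules.drop_post_death_consultations:
        death = out.patients.set_index("patient_id")["death_date"]
        d = out.consultations["patient_id"].map(death)
        late = d.notna() & (out.consultations["date"] > d)
        counts["consultations_after_death"] = int(late.sum())
        out.consultations = out.consultations[~late].reset_index(drop=True)

    if rules.require_age_gender:
        pts = out.patients.set_index("patient_id")
        missing = pts["gender"].isna() | pts["birth_year"].isna()
        bad = out.consultations["patient_id"].map(missing).fillna(False).astype(bool)
        counts["consultations_missing_age_gender"] = int(bad.sum())
        out.consultations = out.consultations[~bad].reset_index(drop=True)

    # prune records linked to dropped consultations
    kept = set(out.consultations["consultation_id"])
    for name in ("therapy", "consult_events"):
        frame = getattr(out, name)
        before = len(frame)
        setattr(out, name, frame[frame["consultation_id"].isin(kept)].reset_index(drop=True))
        counts[f"{name}_orphaned"] = before - len(getattr(out, name))

    for key, n in counts.items():
        if n:
            log.info("eligibility: removed %d %s", n, key)
    merged = dict(out.meta.get("exclusions", {}))
    for key, n in counts.items():
        merged[key] = merged.get(key, 0) + n
    out.meta["exclusions"] = merged
    return out


def active_patients(bundle: EHRBundle, fy: FinancialYear) -> set:
    """Patients registered for at least one day during the financial year
    (closed-interval intersection; an open ``reg_end`` means still registered)."""
    pts = bundle.patients
    reg_end = pts["reg_end"].fillna(pd.Timestamp.max)
    overlap = (pts["reg_start"] <= fy.end) & (reg_end >= fy.start)
    return set(pts.loc[overlap, "patient_id"])


def eligible_index_pool(bundle: EHRBundle, fy: FinancialYear) -> pd.DataFrame:
    """Face-to-face GP consultations within the financial year for active
    patients: the pool the one-per-patient draw samples from."""
    cons = bundle.consultations
    mask = (
        cons["staff_role"].isin(GP_ROLES)
        & (cons["mode"] == "face_to_face")
        & fy.contains(cons["date"])
        & cons["patient_id"].isin(active_patients(bundle, fy))
    )
    return cons[mask]


def sample_index_consultations(
    bundle: EHRBundle, fy: FinancialYear, seed: int
) -> pd.DataFrame:
    """Uniformly draw one eligible consultation per patient for the year.

    Returns an audit frame (patient_id, consultation_id, fy) sorted by
    patient. Candidates are ordered by (date, consultation_id) before the
    seeded draw so the result is independent of storage order; the draw is
    seeded per financial year, so multi-year runs are order-independent too.
    """
    pool = eligible_index_pool(bundle, fy).sort_values(
        ["patient_id", "date", "consultation_id"]
    )
    if pool.empty:
        return pd.DataFrame(columns=["patient_id", "consultation_id", "fy"])
    rng = np.random.default_rng([int(seed), fy.start.year])
    sizes = pool.groupby("patient_id", sort=True).size()
    u = rng.random(len(sizes))
    pick_within = np.floor(u * sizes.to_numpy()).astype(int)
    offsets = np.concatenate([[0], np.cumsum(sizes.to_numpy())[:-1]])
    rows = pool.iloc[offsets + pick_within]
    return pd.DataFrame(
        {
            "patient_id": rows["patient_id"].to_numpy(),
            "consultation_id": rows["consultation_id"].to_numpy(),
            "fy": fy.label,
        }
    )


def sample_index_consultations_all_years(
    bundle: EHRBundle, seed: int, fys: list[FinancialYear] | None = None
) -> pd.DataFrame:
    """One-per-patient draws for every financial year of the study window."""
    if fys is None:
        window = bundle.meta.get("window")
        if window is None:
            raise ValueError("bundle has no study window in meta; pass fys explicitly")
        fys = financial_years(window["start"], window["end"])
    parts = [sample_index_consultations(bundle, fy, seed) for fy in fys]
    parts = [p for p in parts if not p.empty]
    if not parts:
        return pd.DataFrame(columns=["patient_id", "consultation_id", "fy"])
    return pd.concat(parts, ignore_index=True)


def index_events_for_indicators(bundle: EHRBundle, definition, registry=None) -> pd.DataFrame:
    """All (repeated) face-to-face GP consultations satisfying the indicator's
    index predicate on the consultation day. Delegates the predicate to the
    indicator engine."""
    from .indicators import find_index_events

    return find_index_events(bundle, definition, registry)
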