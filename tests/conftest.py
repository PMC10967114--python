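import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from locumcompare.bundle import EHRBundle, empty_table
from locumcompare.codelists import CodelistRegistry

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

_PATIENT_DEFAULTS = {
    "practice_id": "P0001",
    "region": "R1",
    "gender": "F",
    "birth_year": 1960.0,
    "death_date": pd.NaT,
    "reg_start": pd.Timestamp("2000-01-01"),
    "reg_end": pd.NaT,
    "imd_quintile": 3,
    "cm_score": 0.0,
}

_PRACTICE_DEFAULTS = {"region": "R1", "list_size": 7000, "rurality": 1}


def make_bundle(patients=(), consultations=(), therapy=(), clinical=(),
                hospital=(), consult_events=(), practices=None,
                window=("2010-04-01", "2013-03-31"), margin_days=365) -> EHRBundle:
    """Hand-built bundle from row dicts; unspecified fields get defaults."""
    pat_rows = []
    for row in patients:
        full = dict(_PATIENT_DEFAULTS)
        full.update(row)
        pat_rows.append(full)
    pats = pd.DataFrame(pat_rows) if pat_rows else empty_table("patients")
    if pat_rows:
        for col in ("death_date", "reg_start", "reg_end"):
            pats[col] = pd.to_datetime(pats[col])

    if practices is None:
        ids = sorted(set(pats["practice_id"])) if pat_rows else ["P0001"]
        practices = [{"practice_id": p} for p in ids]
    prax_rows = []
    for row in practices:
        full = dict(_PRACTICE_DEFAULTS)
        full.update(row)
        prax_rows.append(full)
    prax = pd.DataFrame(prax_rows)

    def table(rows, name, dates=()):
        if not rows:
            return empty_table(name)
        frame = pd.DataFrame(list(rows))
        for col in dates:
            frame[col] = pd.to_datetime(frame[col])
        for col in empty_table(name).columns:
            if col not in frame.columns:
                frame[col] = "" if col != "date" else pd.NaT
        return frame

    cons = table(
        [{"staff_role": "permanent_gp", "mode": "face_to_face", **row}
         for row in consultations],
        "consultations", dates=("date",),
    )
    meta = {
        "window": {"start": window[0], "end": window[1], "margin_days": margin_days},
        "seed": 0,
    }
    return EHRBundle(
        patients=pats,
        practices=prax,
        consultations=cons,
        therapy=table(therapy, "therapy"),
        clinical=table(clinical, "clinical", dates=("date",)),
        hospital=table(hospital, "hospital", dates=("date",)),
        consult_events=table(consult_events, "consult_events"),
        meta=meta,
    )


@pytest.fixture(scope="session")
def registry() -> CodelistRegistry:
    return CodelistRegistry.default()


@pytest.fixture(scope="session")
def drug_code(registry):
    """First code of each drug group, for terse fixture rows."""
    groups = list(registry.drug_groups()) + []
    return {g: sorted(registry.drug_codes(g))[0] for g in groups}


@pytest.fixture(scope="session")
def cond_code(registry):
    return {c: sorted(registry.condition_codes(c))[0] for c in registry.conditions()}


def random_small_config(rng):
    """A randomised small-cohort configuration for oracle cross-checks."""
    from locumcompare.config import CohortConfig

    return CohortConfig(
        n_regions=2,
        n_practices=int(rng.integers(2, 5)),
        patients_per_practice=int(rng.integers(4, 12)),
        study_start="2010-04-01",
        study_end="2011-03-31",
        consultation_rate=float(rng.uniform(2.0, 6.0)),
        locum_share=float(rng.uniform(0.05, 0.5)),
        other_staff_share=0.2,
        practice_sd=0.2,
        patient_sd=0.3,
        lookback_margin_days=365,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
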