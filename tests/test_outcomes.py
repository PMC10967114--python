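"""Outcome flag construction: window conventions, codelists, multimorbidity,
table assembly, and oracle equivalence on a generated bundle."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import locumcompare as lc
from locumcompare.outcomes import (
    OUTCOME_COLUMNS, build_outcome_table, flag_hospital, flag_prescription,
    flag_referral, flag_revisit, flag_test, round_half_up, summarize_outcomes,
)
from locumcompare.errors import IntegrityError

from conftest import make_bundle
from oracles import BundleView


def one_patient_bundle(consultations=(), **kw):
    rows = [{"consultation_id": "IDX", "patient_id": "T1", "date": "2010-06-01"}]
    rows += list(consultations)
    return make_bundle(patients=[{"patient_id": "T1"}], consultations=rows, **kw)


@pytest.mark.parametrize(
    "offset, mode, expected",
    [
        (7, "face_to_face", 1),   # boundary day inclusive
        (8, "face_to_face", 0),   # outside the window
        (3, "telephone", 1),      # telephone and online revisits count
        (3, "online", 1),
        (0, "face_to_face", 0),   # a second same-day consultation is not a revisit
        (-2, "face_to_face", 0),
    ],
)
def test_revisit_window_days_1_to_7_any_mode(offset, mode, expected):
    date = pd.Timestamp("2010-06-01") + pd.Timedelta(days=offset)
    bundle = one_patient_bundle([
        {"consultation_id": "C2", "patient_id": "T1", "date": date,
         "mode": mode, "staff_role": "other"},
    ])
    assert flag_revisit(bundle, ["IDX"]).iloc[0] == expected


def test_revisit_window_monotone_in_length():
    bundle = one_patient_bundle([
        {"consultation_id": "C2", "patient_id": "T1", "date": "2010-06-11"},
    ])
    assert flag_revisit(bundle, ["IDX"], 7).iloc[0] == 0
    assert flag_revisit(bundle, ["IDX"], 14).iloc[0] == 1


def test_prescription_flags_and_hypnotic_union(registry, drug_code):
    bundle = one_patient_bundle(therapy=[
        {"consultation_id": "IDX", "drug_code": drug_code["z_drug"], "group": "z_drug"},
        {"consultation_id": "IDX", "drug_code": drug_code["nsaid"], "group": "nsaid"},
    ])
    hyp = registry.drug_codelist("hypnotic")
    ab = registry.drug_codelist("antibiotic")
    assert flag_prescription(bundle, ["IDX"], hyp).iloc[0] == 1  # z-drug counts
    assert flag_prescription(bundle, ["IDX"], ab).iloc[0] == 0


def test_hospital_same_day_and_1_7_windows(registry):
    bundle = one_patient_bundle(hospital=[
        {"patient_id": "T1", "date": "2010-06-01",
         "kind": "emergency_admission", "icd10": "S72.0"},
        {"patient_id": "T1", "date": "2010-06-06", "kind": "ae_visit", "icd10": ""},
    ])
    same, later = flag_hospital(bundle, ["IDX"], "emergency_admission", registry)
    assert (same.iloc[0], later.iloc[0]) == (1, 0)
    same, later = flag_hospital(bundle, ["IDX"], "ae_visit", registry)
    assert (same.iloc[0], later.iloc[0]) == (0, 1)


def test_acsc_admission_is_also_an_emergency_admission(registry):
    """An asthma-coded emergency admission 2 days after the index fires both
    the ACSC and the emergency 1-7 day flags."""
    bundle = one_patient_bundle(hospital=[
        {"patient_id": "T1", "date": "2010-06-03",
         "kind": "emergency_admission", "icd10": "J45.9"},
    ])
    _, emerg = flag_hospital(bundle, ["IDX"], "emergency_admission", registry)
    _, acsc = flag_hospital(bundle, ["IDX"], "acsc_admission", registry)
    assert emerg.iloc[0] == 1 and acsc.iloc[0] == 1
    # non-ACSC primary code must not fire the ACSC flag
    bundle2 = one_patient_bundle(hospital=[
        {"patient_id": "T1", "date": "2010-06-03",
         "kind": "emergency_admission", "icd10": "S72.0"},
    ])
    _, acsc2 = flag_hospital(bundle2, ["IDX"], "acsc_admission", registry)
    assert acsc2.iloc[0] == 0


def test_malformed_icd10_skipped_with_warning(registry):
    bundle = one_patient_bundle(hospital=[
        {"patient_id": "T1", "date": "2010-06-03",
         "kind": "emergency_admission", "icd10": ""},
    ])
    with pytest.warns(UserWarning, match="ICD-10"):
        _, acsc = flag_hospital(bundle, ["IDX"], "acsc_admission", registry)
    assert acsc.iloc[0] == 0


def test_test_and_referral_flags():
    bundle = one_patient_bundle(consult_events=[
        {"consultation_id": "IDX", "kind": "referral"},
        {"consultation_id": "IDX", "kind": "test"},
    ])
    assert flag_referral(bundle, ["IDX"]).iloc[0] == 1
    assert flag_test(bundle, ["IDX"]).iloc[0] == 1
    empty = one_patient_bundle()
    assert flag_referral(empty, ["IDX"]).iloc[0] == 0
    assert flag_test(empty, ["IDX"]).iloc[0] == 0


def test_multimorbidity_weighted_sum_and_baseline_cutoff(registry, cond_code):
    w = registry.cm_weights
    bundle = make_bundle(
        patients=[{"patient_id": "T1"}, {"patient_id": "T2"}],
        clinical=[
            {"patient_id": "T1", "date": "2008-01-01", "condition_code": cond_code["asthma"]},
            {"patient_id": "T1", "date": "2010-10-01", "condition_code": cond_code["diabetes"]},
            # recorded after the baseline year: excluded from the score
            {"patient_id": "T1", "date": "2011-02-01", "condition_code": cond_code["copd"]},
        ],
    )
    score = lc.compute_multimorbidity(bundle, registry, baseline_end="2010-12-31")
    assert score["T1"] == pytest.approx(w["asthma"] + w["diabetes"])
    assert score["T2"] == 0.0


def test_build_outcome_table_empty_index():
    bundle = one_patient_bundle()
    table = build_outcome_table(bundle, [])
    assert table.empty
    assert summarize_outcomes(table)["count"].fillna(0).eq(0).all()


def test_build_outcome_table_matches_hand_computed_row(registry, drug_code):
    bundle = make_bundle(
        patients=[{"patient_id": "T1", "birth_year": 1950.0, "gender": "M",
                   "reg_start": "2005-06-01", "imd_quintile": 4}],
        consultations=[
            {"consultation_id": "IDX", "patient_id": "T1", "date": "2010-06-01",
             "staff_role": "locum_gp"},
            {"consultation_id": "C2", "patient_id": "T1", "date": "2010-06-05"},
        ],
        therapy=[{"consultation_id": "IDX", "drug_code": drug_code["antibiotic"],
                  "group": "antibiotic"}],
        hospital=[{"patient_id": "T1", "date": "2010-06-01", "kind": "ae_visit",
                   "icd10": ""}],
    )
    row = build_outcome_table(bundle, ["IDX"], registry).iloc[0]
    assert row["locum"] == 1
    assert row["revisit_7d"] == 1
    assert row["rx_antibiotic"] == 1
    assert row["rx_strong_opioid"] == 0
    assert row["ae_same_day"] == 1 and row["ae_1_7d"] == 0
    assert row["age"] == 60  # fy start year 2010 - 1950
    assert row["fy"] == "2010-2011"
    assert row["imd_quintile"] == 4
    assert row["years_registered"] == pytest.approx(5.0, abs=0.01)


def test_index_referencing_missing_patient_is_integrity_error():
    bundle = one_patient_bundle()
    with pytest.raises(IntegrityError):
        build_outcome_table(bundle, ["NOPE"])


def test_summary_percentages_render_like_published_table():
    """8.18% style: count with comma separators, percent to two decimals."""
    table = pd.DataFrame({
        "locum": [0] * 100, "gender": ["F"] * 100, "age": [50] * 100,
        "cm_score": [0.0] * 100, "years_registered": [10.0] * 100,
        "imd_quintile": [3] * 100, "list_size": [7000] * 100, "rurality": [1] * 100,
        **{c: [0] * 100 for c in OUTCOME_COLUMNS},
    })
    table.loc[:7, "revisit_7d"] = 1  # 8 of 100
    summary = summarize_outcomes(table)
    row = summary[(summary["role"] == "permanent_gp")
                  & (summary["measure"] == "revisit_7d")].iloc[0]
    assert row["display"] == "8(8.00%)"
    assert round_half_up(8.185, 2) == 8.19  # half-up, not banker's
    assert round_half_up(0.125, 2) == 0.13


@given(st.integers(min_value=-400, max_value=400))
def test_time_shift_invariance(shift_days):
    """Shifting every date in the bundle by a constant leaves flags unchanged."""
    def shifted(days):
        base = pd.Timestamp("2010-06-01")
        fmt = lambda off: base + pd.Timedelta(days=days + off)
        return make_bundle(
            patients=[{"patient_id": "T1"}],
            consultations=[
                {"consultation_id": "IDX", "patient_id": "T1", "date": fmt(0)},
                {"consultation_id": "C2", "patient_id": "T1", "date": fmt(5)},
            ],
            hospital=[{"patient_id": "T1", "date": fmt(2), "kind": "ae_visit",
                       "icd10": ""}],
            window=("2008-01-01", "2013-12-31"),
        )
    a, b = shifted(0), shifted(shift_days)
    assert flag_revisit(a, ["IDX"]).iloc[0] == flag_revisit(b, ["IDX"]).iloc[0]
    sa = flag_hospital(a, ["IDX"], "ae_visit")
    sb = flag_hospital(b, ["IDX"], "ae_visit")
    assert (sa[0].iloc[0], sa[1].iloc[0]) == (sb[0].iloc[0], sb[1].iloc[0])


def test_single_event_never_fires_both_windows(registry):
    """One hospital record cannot set both same_day and within_1_7."""
    for offset in range(0, 9):
        bundle = one_patient_bundle(hospital=[
            {"patient_id": "T1",
             "date": pd.Timestamp("2010-06-01") + pd.Timedelta(days=offset),
             "kind": "ae_visit", "icd10": ""},
        ])
        same, later = flag_hospital(bundle, ["IDX"], "ae_visit", registry)
        assert same.iloc[0] + later.iloc[0] <= 1


def test_flags_equal_brute_force_on_generated_bundle(registry):
    cfg = lc.CohortConfig(n_practices=3, patients_per_practice=12,
                          study_end="2011-03-31", seed=17)
    bundle = lc.generate_bundle(cfg)
    idx = lc.sample_index_consultations_all_years(
        lc.filter_eligible(bundle, lc.EligibilityRules(study_start=cfg.study_start)),
        seed=1,
    )
    table = build_outcome_table(bundle, idx, registry).set_index("consultation_id")
    view = BundleView(bundle, registry)
    for cid in table.index:
        expected = view.all_outcome_flags(cid)
        for name, value in expected.items():
            assert table.loc[cid, name] == value, (cid, name)
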