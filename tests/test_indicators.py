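"""Indicator registry, window semantics, episode chaining, rate arithmetic
and engine/oracle equivalence."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import locumcompare as lc
from locumcompare.errors import DefinitionError
from locumcompare.indicators import rate_percent

from conftest import make_bundle, random_small_config
from oracles import BundleView


def test_default_registry_defines_ten_indicators():
    defs = lc.load_registry()
    assert sorted(defs) == list("ABCDEFGHIJ")
    assert defs["A"].min_age == 65
    assert defs["A"].mitigation_groups == ("ulcer_healing",)
    assert defs["A"].lookback_days == 91
    assert defs["J"].trigger_kind == "duration_gt" and defs["J"].min_days == 42
    assert defs["D"].trigger_kind == "co_drug"
    assert defs["G"].trigger_conditions == ("asthma",)


def test_registry_file_override_and_unknown_group(tmp_path):
    text = """
indicators:
  - id: A
    harm: gi_bleed
    index: {drug_groups: [nsaid], min_age: 65}
    trigger: {kind: no_mitigation, mitigation_groups: [ulcer_healing], lookback_days: 60}
"""
    path = tmp_path / "reg.yaml"
    path.write_text(text)
    defs = lc.load_registry(path)
    assert defs["A"].lookback_days == 60

    bad = tmp_path / "bad.yaml"
    bad.write_text(text.replace("nsaid", "not_a_group"))
    with pytest.raises(DefinitionError):
        lc.load_registry(bad)


def _indicator_a_bundle(drug_code, birth_year=1940.0, ppi_days_before=None):
    cons = [{"consultation_id": "IDX", "patient_id": "T1", "date": "2010-08-01"}]
    ther = [{"consultation_id": "IDX", "drug_code": drug_code["nsaid"], "group": "nsaid"}]
    if ppi_days_before is not None:
        date = pd.Timestamp("2010-08-01") - pd.Timedelta(days=ppi_days_before)
        cons.append({"consultation_id": "CPPI", "patient_id": "T1", "date": date,
                     "staff_role": "other"})
        ther.append({"consultation_id": "CPPI", "drug_code": drug_code["ulcer_healing"],
                     "group": "ulcer_healing"})
    return make_bundle(
        patients=[{"patient_id": "T1", "birth_year": birth_year}],
        consultations=cons, therapy=ther,
    )


@pytest.mark.parametrize(
    "ppi_days_before, flag",
    [
        (61, 0),   # gastroprotection ~2 months before: mitigated
        (122, 1),  # ~4 months before: outside the 91-day window, triggers
        (91, 0),   # boundary day inclusive
        (None, 1),
        (0, 0),    # co-prescription on the index day mitigates
    ],
)
def test_indicator_a_mitigation_window(registry, drug_code, ppi_days_before, flag):
    bundle = _indicator_a_bundle(drug_code, ppi_days_before=ppi_days_before)
    defs = lc.load_registry()
    flags = lc.evaluate_indicator(bundle, defs["A"], registry)
    assert len(flags) == 1 and flags["flag"].iloc[0] == flag


@pytest.mark.parametrize("birth_year, in_denominator", [(1946.0, False), (1945.0, True),
                                                        (1930.0, True)])
def test_indicator_a_age_boundary(registry, drug_code, birth_year, in_denominator):
    """Age is the financial-year start year minus birth year; 64 is out."""
    bundle = _indicator_a_bundle(drug_code, birth_year=birth_year)
    defs = lc.load_registry()
    events = lc.index_events_for_indicators(bundle, defs["A"], registry)
    assert (len(events) == 1) is in_denominator


@pytest.mark.parametrize(
    "rx_days_back, flag",
    [
        ((25, 50), 1),   # chained episode spanning 50 days > 42
        ((20,), 0),      # 20-day exposure
        ((40,), 0),      # single gap over grace breaks the chain anyway
        ((21, 42), 0),   # exactly 42 days is not > 6 weeks
        ((21, 43), 1),
        ((), 0),
    ],
)
def test_indicator_j_episode_chaining(registry, drug_code, cond_code, rx_days_back, flag):
    t = pd.Timestamp("2010-10-01")
    cons = [{"consultation_id": "IDX", "patient_id": "T1", "date": t}]
    ther = [{"consultation_id": "IDX", "drug_code": drug_code["antipsychotic"],
             "group": "antipsychotic"}]
    for k, back in enumerate(rx_days_back):
        cons.append({"consultation_id": f"C{k}", "patient_id": "T1",
                     "date": t - pd.Timedelta(days=back), "staff_role": "other"})
        ther.append({"consultation_id": f"C{k}", "drug_code": drug_code["antipsychotic"],
                     "group": "antipsychotic"})
    bundle = make_bundle(
        patients=[{"patient_id": "T1", "birth_year": 1935.0}],
        consultations=cons, therapy=ther,
        clinical=[{"patient_id": "T1", "date": "2009-01-01",
                   "condition_code": cond_code["dementia"]}],
    )
    defs = lc.load_registry()
    flags = lc.evaluate_indicator(bundle, defs["J"], registry)
    assert len(flags) == 1 and flags["flag"].iloc[0] == flag


def test_indicator_j_psychosis_excludes_from_denominator(registry, drug_code, cond_code):
    bundle = make_bundle(
        patients=[{"patient_id": "T1", "birth_year": 1935.0}],
        consultations=[{"consultation_id": "IDX", "patient_id": "T1",
                        "date": "2010-10-01"}],
        therapy=[{"consultation_id": "IDX", "drug_code": drug_code["antipsychotic"],
                  "group": "antipsychotic"}],
        clinical=[
            {"patient_id": "T1", "date": "2009-01-01",
             "condition_code": cond_code["dementia"]},
            {"patient_id": "T1", "date": "2009-06-01",
             "condition_code": cond_code["psychosis"]},
        ],
    )
    defs = lc.load_registry()
    assert lc.index_events_for_indicators(bundle, defs["J"], registry).empty


def test_indicator_d_coverage_window(registry, drug_code):
    """Warfarin at index triggers when an NSAID prescription covers the index
    date (28-day coverage, inclusive)."""
    def bundle_with_nsaid(days_back):
        cons = [{"consultation_id": "IDX", "patient_id": "T1", "date": "2010-08-01"}]
        ther = [{"consultation_id": "IDX", "drug_code": drug_code["anticoagulant"],
                 "group": "anticoagulant"}]
        if days_back is not None:
            cons.append({"consultation_id": "CN", "patient_id": "T1",
                         "date": pd.Timestamp("2010-08-01") - pd.Timedelta(days=days_back),
                         "staff_role": "other"})
            ther.append({"consultation_id": "CN", "drug_code": drug_code["nsaid"],
                         "group": "nsaid"})
        return make_bundle(patients=[{"patient_id": "T1"}],
                           consultations=cons, therapy=ther)

    defs = lc.load_registry()
    for days_back, expected in ((None, 0), (28, 1), (29, 0), (0, 1)):
        flags = lc.evaluate_indicator(bundle_with_nsaid(days_back), defs["D"], registry)
        assert flags["flag"].iloc[0] == expected, days_back


def test_widening_mitigation_lookback_never_increases_numerator(registry, drug_code):
    from dataclasses import replace

    bundle = _indicator_a_bundle(drug_code, ppi_days_before=122)
    defs = lc.load_registry()
    narrow = lc.evaluate_indicator(bundle, defs["A"], registry)["flag"].sum()
    wide = lc.evaluate_indicator(
        bundle, replace(defs["A"], lookback_days=150), registry)["flag"].sum()
    assert wide <= narrow


# ---------------------------------------------------------------------------
# rate arithmetic

@pytest.mark.parametrize(
    "num, den, decimals, expected",
    [
        (237_867, 420_760, 1, 56.5),
        (5601, 5972, 1, 93.8),
        (0, 10, 1, 0.0),
        (1, 1600, 2, 0.06),
        (1, 8, 1, 12.5),
    ],
)
def test_rate_percent_round_half_up(num, den, decimals, expected):
    assert rate_percent(num, den, decimals) == expected


def test_rate_percent_undefined_for_zero_denominator():
    with pytest.raises(ZeroDivisionError):
        rate_percent(1, 0)
    flags = pd.DataFrame({"role": [], "flag": []})
    for res in lc.compute_results(flags, "A"):
        assert res.rate is None and res.denominator == 0


@given(st.integers(0, 1000), st.integers(1, 1000))
def test_rate_bounds(num_raw, den):
    num = min(num_raw, den)
    rate = rate_percent(num, den)
    assert 0.0 <= rate <= 100.0


def test_role_split_partitions_denominators(registry):
    cfg = random_small_config(np.random.default_rng(8))
    bundle = lc.generate_bundle(cfg)
    defs = lc.load_registry()
    for ind_id, defn in defs.items():
        events = lc.index_events_for_indicators(bundle, defn, registry)
        flags = lc.evaluate_indicator(bundle, defn, registry, events)
        results = lc.compute_results(flags, ind_id)
        assert sum(r.denominator for r in results) == len(events)
        for r in results:
            assert 0 <= r.numerator <= r.denominator


def test_engine_matches_brute_force_oracle(registry):
    """Every index event and trigger flag equals an independent row scan."""
    rng = np.random.default_rng(123)
    defs = lc.load_registry()
    for _ in range(3):
        cfg = random_small_config(rng)
        bundle = lc.generate_bundle(cfg)
        view = BundleView(bundle, registry)
        for defn in defs.values():
            expected = sorted(view.indicator_results(defn))
            flags = lc.evaluate_indicator(bundle, defn, registry)
            got = sorted(zip(flags["consultation_id"], flags["role"], flags["flag"]))
            assert got == expected, defn.id
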