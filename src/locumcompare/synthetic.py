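"""Seeded generator of CPRD-GOLD-like bundles with known ground truth.

Consultation outcomes follow a logistic model

    logit(p) = intercept_o + locum * beta_o + x' gamma + u_practice + u_patient

with independent Gaussian practice and patient intercepts, so downstream
stages (cohort sampling, outcome flagging, multilevel estimation) can be
tested for parameter recovery without restricted data. Consultation counts
per patient-year are Poisson with dates uniform over each patient's active
period; locum/permanent staffing is per-consultation Bernoulli, optionally
confounded with multimorbidity.

Outcome events materialise as records: prescriptions become therapy rows,
tests/referrals become consultation-linked event rows, revisits insert a
follow-up consultation 1..7 days later (staffed by "other" so it never enters
an index set), and hospital outcomes insert HES-like rows on day 0 or days
1..7 (ACSC admissions carry an ACSC ICD-10 primary code). Events falling
after the study end or the patient's death are censored (dropped), as they
would be in a real extract.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .bundle import EHRBundle, empty_table
from .codelists import CodelistRegistry
from .config import CohortConfig, TruthTable, standardise_covariates
from .errors import CapacityError, ConfigurationError
from .periods import fy_start_year

_NON_ACSC_CODES = ("S72.0", "K35.8", "N39.0", "R07.4", "A09", "M54.5")

# conditions whose recorded prevalence scales with age in the generator
_AGE_SCALED = {
    "heart_failure", "dementia", "copd", "hypertension", "ckd",
    "atrial_fibrillation", "coronary_heart_disease", "diabetes",
}


def _days(ts: pd.Timestamp) -> int:
    return ts.to_datetime64().astype("datetime64[D]").astype(int)


def _dates_from_days(days: np.ndarray) -> pd.Series:
    return pd.Series(days.astype("datetime64[D]").astype("datetime64[ns]"))


def generate_bundle(
    config: CohortConfig,
    truth: TruthTable | None = None,
    registry: CodelistRegistry | None = None,
) -> EHRBundle:
    """Generate one bundle; identical (config, truth) give identical output."""
    truth = truth if truth is not None else TruthTable()
    config.validate()
    truth.validate()
    registry = registry or CodelistRegistry.default()
    rng = np.random.default_rng(int(config.seed))

    start_d = _days(config.study_start)
    end_d = _days(config.study_end)
    margin_lo = start_d - int(config.lookback_margin_days)
    mid_year = float(np.mean(fy_start_year([config.study_start, config.study_end])))
    baseline_end = pd.Timestamp(year=config.study_start.year, month=12, day=31)

    meta = {
        "seed": int(config.seed),
        "window": {
            "start": str(config.study_start.date()),
            "end": str(config.study_end.date()),
            "margin_days": int(config.lookback_margin_days),
        },
        "mid_year": mid_year,
        "baseline_end": str(baseline_end.date()),
        "truth": {
            "intercepts": dict(truth.intercepts),
            "locum_effects": dict(truth.locum_effects),
            "covariate_effects": dict(truth.covariate_effects),
        },
    }

    # ---------------- practices ----------------
    n_pr = config.n_practices
    practice_id = np.array([f"P{i:04d}" for i in range(n_pr)])
    region = np.array([f"R{(i % config.n_regions) + 1}" for i in range(n_pr)])
    list_size = np.maximum(500, rng.normal(7020.0, 3493.0, n_pr)).astype(int)
    rurality = 1 + (rng.random(n_pr) < 0.15).astype(int)
    practices = pd.DataFrame(
        {"practice_id": practice_id, "region": region,
         "list_size": list_size, "rurality": rurality}
    )
    practice_re = rng.normal(0.0, config.practice_sd, n_pr) if config.practice_sd else np.zeros(n_pr)

    # ---------------- patients ----------------
    n_per = rng.poisson(config.patients_per_practice, n_pr)
    n_pat = int(n_per.sum())
    pat_practice = np.repeat(np.arange(n_pr), n_per)
    patient_id = np.array([f"T{i:07d}" for i in range(n_pat)])

    gender = np.where(rng.random(n_pat) < 0.55, "F", "M")
    age0 = np.clip(rng.normal(46.0, 23.7, n_pat), 0.0, 95.0)
    birth_year = (config.study_start.year - age0).astype(int)
    miss_g = rng.random(n_pat) < config.missing_age_gender_rate / 2.0
    miss_b = rng.random(n_pat) < config.missing_age_gender_rate / 2.0
    gender = pd.Series(gender).mask(miss_g, other=pd.NA)
    birth_year_f = pd.Series(birth_year, dtype="float64").mask(miss_b)
    imd = rng.integers(1, 6, n_pat)

    # registration: most patients registered long before the window
    new_joiner = rng.random(n_pat) < 0.10
    tenure_days = rng.exponential(16.4 * 365.25, n_pat).astype(int)
    reg_start_d = start_d - tenure_days
    join_span = max(end_d - 30 - start_d, 1)
    reg_start_d = np.where(
        new_joiner, start_d + rng.integers(0, join_span, n_pat), reg_start_d
    )
    birth_floor = ((birth_year - 1970) * 365.25).astype(int)
    reg_start_d = np.maximum(reg_start_d, birth_floor)
    dereg = rng.random(n_pat) < 0.08
    reg_end_d = np.where(
        dereg,
        np.minimum(end_d, reg_start_d + 30 + rng.integers(0, 365 * 10, n_pat)),
        np.iinfo(np.int32).max,
    )

    years_window = (end_d - start_d) / 365.25
    hazard = config.annual_death_rate * np.exp((age0 - 46.0) / 12.0)
    p_death = 1.0 - np.exp(-hazard * years_window)
    dies = rng.random(n_pat) < p_death
    death_d = np.where(
        dies, start_d + rng.integers(0, max(end_d - start_d, 1), n_pat),
        np.iinfo(np.int32).max,
    )

    # recorded conditions
    clin_pat, clin_date, clin_code = [], [], []
    cond_first_baseline = {}
    for cond in sorted(config.condition_prevalence):
        prev = config.condition_prevalence[cond]
        p = np.full(n_pat, prev)
        if cond in _AGE_SCALED:
            p = np.clip(prev * np.exp((age0 - 46.0) / 25.0), 0.0, 0.95)
        has = rng.random(n_pat) < p
        pre_study = rng.random(n_pat) < 0.80
        offset = (rng.random(n_pat) * 15 * 365.25).astype(int) + 36
        date_d = np.where(pre_study, start_d - offset,
                          start_d + rng.integers(0, max(end_d - start_d, 1), n_pat))
        date_d = np.maximum(date_d, np.maximum(birth_floor, margin_lo))
        date_d = np.minimum(date_d, np.minimum(death_d, end_d))
        has &= date_d <= death_d
        idx = np.flatnonzero(has)
        code = sorted(registry.condition_codes(cond))[0]
        clin_pat.append(patient_id[idx])
        clin_date.append(date_d[idx])
        clin_code.extend([code] * len(idx))
        flag = np.zeros(n_pat, dtype=bool)
        flag[idx] = date_d[idx] <= _days(baseline_end)
        cond_first_baseline[cond] = flag

    cm_score = np.zeros(n_pat)
    for cond, flag in cond_first_baseline.items():
        cm_score += registry.weight_for(cond) * flag

    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "practice_id": practice_id[pat_practice] if n_pat else np.array([], dtype=object),
            "region": region[pat_practice] if n_pat else np.array([], dtype=object),
            "gender": gender,
            "birth_year": birth_year_f,
            "death_date": _dates_from_days(np.where(dies, death_d, np.datetime64("NaT").astype(int)))
            if n_pat else pd.Series(dtype="datetime64[ns]"),
            "reg_start": _dates_from_days(reg_start_d) if n_pat else pd.Series(dtype="datetime64[ns]"),
            "reg_end": _dates_from_days(np.where(dereg, reg_end_d, np.datetime64("NaT").astype(int)))
            if n_pat else pd.Series(dtype="datetime64[ns]"),
            "imd_quintile": imd if n_pat else np.array([], dtype=int),
            "cm_score": cm_score if n_pat else np.array([], dtype=float),
        }
    )
    patient_re = rng.normal(0.0, config.patient_sd, n_pat) if config.patient_sd else np.zeros(n_pat)

    clinical = pd.DataFrame(
        {
            "patient_id": np.concatenate(clin_pat) if clin_pat else np.array([], dtype=object),
            "date": _dates_from_days(np.concatenate(clin_date)) if clin_date
            else pd.Series(dtype="datetime64[ns]"),
            "condition_code": clin_code,
        }
    )

    # ---------------- consultations ----------------
    active_lo = np.maximum(reg_start_d, margin_lo)
    active_hi = np.minimum.reduce([np.full(n_pat, end_d), reg_end_d, death_d]) if n_pat else np.array([], dtype=int)
    active_days = np.maximum(active_hi - active_lo + 1, 0)
    n_cons = rng.poisson(config.consultation_rate * active_days / 365.25) if n_pat else np.array([], dtype=int)
    total = int(n_cons.sum())
    cons_pat = np.repeat(np.arange(n_pat), n_cons)
    cons_date_d = active_lo[cons_pat] + (rng.random(total) * active_days[cons_pat]).astype(int)

    u_role = rng.random(total)
    is_other = u_role < config.other_staff_share
    if config.locum_share <= 0.0:
        p_locum = np.zeros(total)
    elif config.locum_share >= 1.0:
        p_locum = np.ones(total)
    else:
        p_locum = expit(
            logit(config.locum_share)
            + config.locum_confounding * cm_score[cons_pat]
        )
    is_locum = (~is_other) & (rng.random(total) < p_locum)
    role = np.where(is_other, "other", np.where(is_locum, "locum_gp", "permanent_gp"))
    u_mode = rng.random(total)
    rest = 1.0 - config.face_to_face_share
    mode = np.where(
        u_mode < config.face_to_face_share, "face_to_face",
        np.where(u_mode < config.face_to_face_share + 0.9 * rest, "telephone", "online"),
    )
    cons_id = np.array([f"C{i:08d}" for i in range(total)])

    # ---------------- outcome draws ----------------
    fy_year = fy_start_year(_dates_from_days(cons_date_d)) if total else np.array([], dtype=int)
    age_at = fy_year - np.where(np.isnan(birth_year_f.to_numpy()), config.study_start.year - 46,
                                birth_year_f.to_numpy())[cons_pat] if total else np.array([])
    cov_frame = pd.DataFrame(
        {
            "age": age_at,
            "gender": pd.Series(gender).fillna("M").to_numpy()[cons_pat] if total else [],
            "cm_score": cm_score[cons_pat] if total else [],
            "imd_quintile": imd[cons_pat] if total else [],
            "years_registered": (cons_date_d - reg_start_d[cons_pat]) / 365.25 if total else [],
            "list_size": list_size[pat_practice][cons_pat] if total else [],
            "fy_year": fy_year,
        }
    )
    x_std = standardise_covariates(cov_frame, mid_year) if total else None
    gamma = truth.covariate_effects
    lp_base = np.zeros(total)
    if total:
        for name in x_std.columns:
            coef = gamma.get(name, 0.0)
            if coef:
                lp_base += coef * x_std[name].to_numpy()
        lp_base += practice_re[pat_practice][cons_pat] + patient_re[cons_pat]

    ther_cons, ther_code, ther_group = [], [], []
    ev_cons, ev_kind = [], []
    hosp_pat, hosp_date, hosp_kind, hosp_icd = [], [], [], []
    extra_cons = []  # follow-up (revisit) consultation rows

    def _sample_codes(group, k):
        codes = sorted(registry.drug_codes(group))
        return [codes[i] for i in rng.integers(0, len(codes), k)]

    group_of = registry.code_to_group()
    acsc_pool = tuple(registry.acsc_prefixes)

    for outcome in sorted(truth.intercepts):
        a = truth.intercepts[outcome]
        b = truth.locum_effects.get(outcome, 0.0)
        if not total:
            continue
        p = expit(a + b * is_locum.astype(float) + lp_base)
        fired = np.flatnonzero(rng.random(total) < p)
        if outcome.startswith("rx_"):
            group = {"rx_antibiotic": "antibiotic",
                     "rx_strong_opioid": "strong_opioid",
                     "rx_hypnotic": "hypnotic"}[outcome]
            codes = _sample_codes(group, len(fired))
            ther_cons.extend(cons_id[fired])
            ther_code.extend(codes)
            ther_group.extend(group_of[c] for c in codes)
        elif outcome in ("test", "referral"):
            ev_cons.extend(cons_id[fired])
            ev_kind.extend([outcome] * len(fired))
        elif outcome == "revisit_7d":
            offs = rng.integers(1, 8, len(fired))
            rdate = cons_date_d[fired] + offs
            ok = (rdate <= np.minimum(active_hi[cons_pat[fired]], end_d))
            extra_cons.append((cons_pat[fired][ok], rdate[ok]))
        else:
            kind, when = {
                "ae_same_day": ("ae_visit", 0),
                "ae_1_7d": ("ae_visit", 1),
                "emerg_same_day": ("emergency_admission", 0),
                "emerg_1_7d": ("emergency_admission", 1),
                "acsc_same_day": ("emergency_admission", 0),
                "acsc_1_7d": ("emergency_admission", 1),
            }[outcome]
            offs = rng.integers(1, 8, len(fired)) if when else np.zeros(len(fired), dtype=int)
            hdate = cons_date_d[fired] + offs
            ok = hdate <= np.minimum(death_d[cons_pat[fired]], end_d)
            k = int(ok.sum())
            hosp_pat.extend(patient_id[cons_pat[fired]][ok])
            hosp_date.extend(hdate[ok])
            hosp_kind.extend([kind] * k)
            if outcome.startswith("acsc"):
                hosp_icd.extend(acsc_pool[i] for i in rng.integers(0, len(acsc_pool), k))
            elif kind == "emergency_admission":
                hosp_icd.extend(_NON_ACSC_CODES[i]
                                for i in rng.integers(0, len(_NON_ACSC_CODES), k))
            else:
                hosp_icd.extend([""] * k)

    # follow-up consultations for fired revisits
    if extra_cons:
        f_pat = np.concatenate([p for p, _ in extra_cons])
        f_date = np.concatenate([d for _, d in extra_cons])
    else:
        f_pat = np.array([], dtype=int)
        f_date = np.array([], dtype=int)
    f_id = np.array([f"F{i:08d}" for i in range(len(f_pat))])

    all_cons = pd.DataFrame(
        {
            "consultation_id": np.concatenate([cons_id, f_id]),
            "patient_id": np.concatenate([patient_id[cons_pat], patient_id[f_pat]])
            if n_pat else np.array([], dtype=object),
            "date": _dates_from_days(np.concatenate([cons_date_d, f_date])),
            "staff_role": np.concatenate([role, np.full(len(f_pat), "other")]),
            "mode": np.concatenate([mode, np.full(len(f_pat), "face_to_face")]),
        }
    )

    # background prescribing (indicator-relevant drug groups)
    n_all = len(all_cons)
    for group in sorted(config.background_rx):
        prob = config.background_rx[group]
        if prob <= 0 or n_all == 0:
            continue
        fired = np.flatnonzero(rng.random(n_all) < prob)
        codes = _sample_codes(group, len(fired))
        ther_cons.extend(all_cons["consultation_id"].to_numpy()[fired])
        ther_code.extend(codes)
        ther_group.extend([group] * len(fired))

    therapy = pd.DataFrame(
        {"consultation_id": ther_cons, "drug_code": ther_code, "group": ther_group}
    )
    consult_events = pd.DataFrame({"consultation_id": ev_cons, "kind": ev_kind})
    hospital = pd.DataFrame(
        {
            "patient_id": hosp_pat,
            "date": _dates_from_days(np.asarray(hosp_date, dtype=int))
            if hosp_date else pd.Series(dtype="datetime64[ns]"),
            "kind": hosp_kind,
            "icd10": hosp_icd,
        }
    )

    bundle = EHRBundle(
        patients=patients if n_pat else empty_table("patients"),
        practices=practices,
        consultations=all_cons if n_all else empty_table("consultations"),
        therapy=therapy if len(therapy) else empty_table("therapy"),
        clinical=clinical if len(clinical) else empty_table("clinical"),
        hospital=hospital if len(hospital) else empty_table("hospital"),
        consult_events=consult_events if len(consult_events) else empty_table("consult_events"),
        meta=meta,
    )
    return bundle


# ----------------------------------------------------------------------
# scenario injection for the prescribing-safety indicators

# per-indicator recipes: which drug goes on the index consultation, which
# condition history / prior prescriptions define the at-risk and triggered
# states, and which prior prescription cancels the trigger
_RECIPES = {
    "A": dict(index_group="nsaid", min_age=65, conditions=(),
              risk_rx=(), mitigation=("ulcer_healing", 30)),
    "B": dict(index_group="nsaid", max_age=64, conditions=("peptic_ulcer",),
              risk_rx=(), mitigation=("ulcer_healing", 30)),
    "C": dict(index_group="antiplatelet_nonaspirin", conditions=("peptic_ulcer",),
              risk_rx=(), mitigation=("ulcer_healing", 30)),
    "D": dict(index_group="anticoagulant", conditions=(),
              risk_rx=(("nsaid", 10),), mitigation=None),
    "E": dict(index_group="antiplatelet_nonaspirin", conditions=(),
              risk_rx=(("anticoagulant", 10),), mitigation=("ulcer_healing", 30)),
    "F": dict(index_group="aspirin", conditions=(),
              risk_rx=(("antiplatelet_nonaspirin", 10),), mitigation=("ulcer_healing", 30)),
    "G": dict(index_group="nonselective_beta_blocker", conditions=(),
              risk_condition="asthma", mitigation=None),
    "H": dict(index_group="laba", conditions=("asthma",),
              risk_rx=(), mitigation=("ics", 30)),
    "I": dict(index_group="nsaid", max_age=64, conditions=(),
              risk_condition="heart_failure", mitigation=None),
    "J": dict(index_group="antipsychotic", min_age=65, conditions=("dementia",),
              episode_triggered=(25, 50), episode_short=(20,), mitigation=None),
}

# conditions that must be absent from a host unless the recipe injects them
_INDICATOR_CONDITIONS = ("asthma", "peptic_ulcer", "heart_failure", "dementia", "psychosis")
_INDICATOR_GROUPS = (
    "nsaid", "ulcer_healing", "anticoagulant", "antiplatelet_nonaspirin",
    "aspirin", "nonselective_beta_blocker", "laba", "ics", "antipsychotic",
)


def inject_indicator_scenarios(
    bundle: EHRBundle,
    scenario_spec: dict,
    seed: int,
    registry: CodelistRegistry | None = None,
    lookback_days: int = 91,
) -> EHRBundle:
    """Augment a bundle with known triggered/mitigated indicator cases.

    ``scenario_spec`` maps indicator id -> role -> counts, e.g.
    ``{"A": {"locum_gp": {"triggered": 5, "mitigated": 3}}}``; an optional
    ``boundary_mitigated`` count places the mitigating prescription exactly
    ``lookback_days`` before the index (the window is inclusive, so such
    cases classify as mitigated).

    Each case is hosted by a distinct suitable patient (alive, registered
    around the case date, free of indicator-relevant history); supporting
    prescriptions attach to "other"-staff consultations so only the intended
    index event enters an indicator denominator. Exact count recovery holds
    on bundles without organic indicator-relevant prescribing; on other
    bundles injected cases add to the organic counts. Ground-truth labels are
    kept on ``bundle.scenario_truth``.

    Raises CapacityError when too few suitable patients exist.
    """
    registry = registry or CodelistRegistry.default()
    rng = np.random.default_rng(int(seed))
    out = bundle.copy()

    for ind, per_role in scenario_spec.items():
        if ind not in _RECIPES:
            raise ConfigurationError(f"unknown indicator id {ind!r}")
        for role, counts in per_role.items():
            if role not in ("permanent_gp", "locum_gp"):
                raise ConfigurationError(f"unknown role {role!r}")
            for key, n in counts.items():
                if key not in ("triggered", "mitigated", "boundary_mitigated"):
                    raise ConfigurationError(f"unknown scenario label {key!r}")
                if n < 0:
                    raise ConfigurationError("scenario counts must be >= 0")

    window = out.meta.get("window", {})
    study_start = pd.Timestamp(window.get("start", out.consultations["date"].min()))
    study_end = pd.Timestamp(window.get("end", out.consultations["date"].max()))
    margin = int(window.get("margin_days", 0))

    pts = out.patients
    if pts.empty:
        if any(n for per_role in scenario_spec.values()
               for counts in per_role.values() for n in counts.values()):
            raise CapacityError("no patients available to host scenarios")
        out.scenario_truth = _truth_frame([])
        return out

    reg_start = pts["reg_start"]
    reg_end = pts["reg_end"].fillna(study_end)
    death = pts["death_date"].fillna(study_end + pd.Timedelta(days=1))
    lo = reg_start.clip(lower=study_start)
    hi = pd.concat([reg_end, death - pd.Timedelta(days=1),
                    pd.Series(study_end, index=pts.index)], axis=1).min(axis=1)
    span_ok = (hi - lo).dt.days >= 320
    base_date = lo + pd.Timedelta(days=160)

    cond_codes = {c: sorted(registry.condition_codes(c))[0] for c in registry.conditions()}
    code_cond = registry.code_to_condition()
    has_cond = {c: set() for c in _INDICATOR_CONDITIONS}
    for code, grp in zip(out.clinical["condition_code"], out.clinical["patient_id"]):
        cond = code_cond.get(code)
        if cond in has_cond:
            has_cond[cond].add(grp)
    # patients with any indicator-relevant prescription anywhere
    dirty = set(
        out.therapy.loc[out.therapy["group"].isin(_INDICATOR_GROUPS), "consultation_id"]
        .map(out.consultations.set_index("consultation_id")["patient_id"])
        .dropna()
    )

    age_at_base = (
        np.asarray(fy_start_year(base_date.fillna(study_start)))
        - pts["birth_year"].to_numpy(dtype=float)
    )
    usable = (
        span_ok.to_numpy()
        & pts["gender"].notna().to_numpy()
        & pts["birth_year"].notna().to_numpy()
        & ~pts["patient_id"].isin(dirty).to_numpy()
    )
    for cond, owners in has_cond.items():
        usable &= ~pts["patient_id"].isin(owners).to_numpy()

    order = rng.permutation(np.flatnonzero(usable))
    cursor = {"i": 0}

    def _claim(min_age=None, max_age=None) -> int:
        while cursor["i"] < len(order):
            j = order[cursor["i"]]
            cursor["i"] += 1
            a = age_at_base[j]
            if min_age is not None and not a >= min_age:
                continue
            if max_age is not None and not a <= max_age:
                continue
            return int(j)
        raise CapacityError("not enough suitable patients to host scenarios")

    new_cons, new_ther, new_clin, truth_rows = [], [], [], []
    seq = {"c": 0}
    drug_code = {g: sorted(registry.drug_codes(g))[0] for g in _INDICATOR_GROUPS}
    window_lo = study_start - pd.Timedelta(days=margin)

    def _add_consult(patient, date, role_, with_rx=None):
        seq["c"] += 1
        cid = f"S{seq['c']:07d}"
        new_cons.append((cid, patient, date, role_, "face_to_face"))
        if with_rx:
            new_ther.append((cid, drug_code[with_rx], with_rx))
        return cid

    for ind in sorted(scenario_spec):
        recipe = _RECIPES[ind]
        for role in sorted(scenario_spec[ind]):
            counts = scenario_spec[ind][role]
            cases = (
                [("triggered", False)] * counts.get("triggered", 0)
                + [("mitigated", False)] * counts.get("mitigated", 0)
                + [("mitigated", True)] * counts.get("boundary_mitigated", 0)
            )
            for label, at_boundary in cases:
                j = _claim(recipe.get("min_age"), recipe.get("max_age"))
                patient = pts["patient_id"].iat[j]
                t = base_date.iat[j]

                for cond in recipe.get("conditions", ()):
                    cdate = max(t - pd.Timedelta(days=400), window_lo)
                    new_clin.append((patient, cdate, cond_codes[cond]))
                cid = _add_consult(patient, t, role, with_rx=recipe["index_group"])

                if "episode_triggered" in recipe:  # indicator J
                    backs = recipe["episode_triggered" if label == "triggered"
                                   else "episode_short"]
                    for days_back in backs:
                        _add_consult(patient, t - pd.Timedelta(days=days_back),
                                     "other", with_rx=recipe["index_group"])
                elif "risk_condition" in recipe:  # G, I: condition is the trigger
                    if label == "triggered":
                        cdate = max(t - pd.Timedelta(days=400), window_lo)
                        new_clin.append((patient, cdate, cond_codes[recipe["risk_condition"]]))
                else:
                    for group, days_back in recipe.get("risk_rx", ()):
                        # D: the co-prescription *is* the trigger
                        if recipe["mitigation"] is None and label != "triggered":
                            continue
                        _add_consult(patient, t - pd.Timedelta(days=days_back),
                                     "other", with_rx=group)
                    if recipe["mitigation"] is not None and label == "mitigated":
                        group, days_back = recipe["mitigation"]
                        if at_boundary:
                            days_back = lookback_days
                        _add_consult(patient, t - pd.Timedelta(days=days_back),
                                     "other", with_rx=group)

                truth_rows.append((ind, role, cid, patient, label))

    if new_cons:
        out.consultations = pd.concat(
            [out.consultations,
             pd.DataFrame(new_cons, columns=["consultation_id", "patient_id",
                                             "date", "staff_role", "mode"])],
            ignore_index=True,
        )
    if new_ther:
        out.therapy = pd.concat(
            [out.therapy,
             pd.DataFrame(new_ther, columns=["consultation_id", "drug_code", "group"])],
            ignore_index=True,
        )
    if new_clin:
        out.clinical = pd.concat(
            [out.clinical,
             pd.DataFrame(new_clin, columns=["patient_id", "date", "condition_code"])],
            ignore_index=True,
        )
    out.scenario_truth = _truth_frame(truth_rows)
    return out


def _truth_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["indicator", "role", "consultation_id", "patient_id", "label"]
    )
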