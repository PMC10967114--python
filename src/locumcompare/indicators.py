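"""Evaluation of the ten prescribing-safety indicators (A..J) over repeated
consultation index events, yielding per-role numerators, denominators and
rates.

An indicator is declarative: an *index predicate* selects the at-risk
face-to-face GP consultations (drug group prescribed that day, optional age
bound, condition history requirements, concurrent co-prescription), and a
*trigger* decides which of those count as potentially hazardous. All windows
are inclusive at both ends and measured in calendar days; prescription dates
are the dates of the consultations they are linked to.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .bundle import EHRBundle, GP_ROLES
from .codelists import CodelistRegistry
from .errors import DefinitionError
from .periods import fy_start_year

TRIGGER_KINDS = ("no_mitigation", "condition_present", "co_drug", "duration_gt")


@dataclass(frozen=True)
class IndicatorDefinition:
    """Operational definition of one prescribing-safety indicator."""

    id: str
    harm: str
    description: str = ""
    # index (at-risk) predicate
    index_drug_groups: tuple = ()
    min_age: int | None = None
    conditions: tuple = ()
    conditions_absent: tuple = ()
    co_drug_groups: tuple = ()
    co_coverage_days: int = 28
    # trigger
    trigger_kind: str = "no_mitigation"
    mitigation_groups: tuple = ()
    lookback_days: int = 91
    trigger_conditions: tuple = ()
    trigger_co_groups: tuple = ()
    coverage_days: int = 28
    duration_group: str | None = None
    min_days: int = 42
    grace_days: int = 28


@dataclass(frozen=True)
class IndicatorResult:
    """Numerator/denominator/rate for one indicator and prescriber role."""

    indicator: str
    role: str
    numerator: int
    denominator: int

    @property
    def rate(self):
        if self.denominator == 0:
            return None
        return rate_percent(self.numerator, self.denominator)


def rate_percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals`` places
    (the convention of the published tables)."""
    if denominator == 0:
        raise ZeroDivisionError("rate undefined for zero denominator")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(q, ROUND_HALF_UP)
    return float(value)


# ----------------------------------------------------------------------
# registry loading

def _tupled(value) -> tuple:
    if value is None:
        return ()
    if isinstance(value, (list, tuple)):
        return tuple(value)
    return (value,)


def load_registry(path=None, codelists: CodelistRegistry | None = None) -> dict:
    """Load indicator definitions from a YAML registry file (the packaged
    default defines A..J). Returns ``{id: IndicatorDefinition}``; definitions
    referencing unknown drug or condition groups raise DefinitionError."""
    if path is None:
        with resources.files("locumcompare.data").joinpath("indicators.yaml").open("r") as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    codelists = codelists or CodelistRegistry.default()
    known_groups = codelists.drug_groups() | {"hypnotic"}
    known_conditions = codelists.conditions()

    defs = {}
    for entry in raw.get("indicators", []):
        try:
            ind_id = entry["id"]
            index = entry.get("index") or {}
            trigger = entry["trigger"]
            kind = trigger["kind"]
        except KeyError as exc:
            raise DefinitionError(f"indicator entry missing field {exc}") from exc
        if ind_id in defs:
            raise DefinitionError(f"duplicate indicator id {ind_id!r}")
        if kind not in TRIGGER_KINDS:
            raise DefinitionError(f"indicator {ind_id}: unknown trigger kind {kind!r}")
        if not index.get("drug_groups"):
            raise DefinitionError(f"indicator {ind_id}: index predicate needs drug_groups")

        defn = IndicatorDefinition(
            id=str(ind_id),
            harm=entry.get("harm", ""),
            description=entry.get("description", ""),
            index_drug_groups=_tupled(index.get("drug_groups")),
            min_age=index.get("min_age"),
            conditions=_tupled(index.get("conditions")),
            conditions_absent=_tupled(index.get("conditions_absent")),
            co_drug_groups=_tupled(index.get("co_drug_groups")),
            co_coverage_days=int(index.get("co_coverage_days", 28)),
            trigger_kind=kind,
            mitigation_groups=_tupled(trigger.get("mitigation_groups")),
            lookback_days=int(trigger.get("lookback_days", 91)),
            trigger_conditions=_tupled(trigger.get("conditions")),
            trigger_co_groups=_tupled(trigger.get("co_drug_groups")),
            coverage_days=int(trigger.get("coverage_days", 28)),
            duration_group=trigger.get("duration_group"),
            min_days=int(trigger.get("min_days", 42)),
            grace_days=int(trigger.get("grace_days", 28)),
        )
        for window in (defn.lookback_days, defn.coverage_days,
                       defn.co_coverage_days, defn.grace_days):
            if window <= 0:
                raise DefinitionError(f"indicator {ind_id}: windows must be > 0")
        groups = (set(defn.index_drug_groups) | set(defn.co_drug_groups)
                  | set(defn.mitigation_groups) | set(defn.trigger_co_groups))
        if defn.duration_group:
            groups.add(defn.duration_group)
        unknown = groups - known_groups
        if unknown:
            raise DefinitionError(
                f"indicator {ind_id}: unknown drug group(s) {sorted(unknown)}"
            )
        unknown = (set(defn.conditions) | set(defn.conditions_absent)
                   | set(defn.trigger_conditions)) - known_conditions
        if unknown:
            raise DefinitionError(
                f"indicator {ind_id}: unknown condition(s) {sorted(unknown)}"
            )
        if kind == "no_mitigation" and not defn.mitigation_groups:
            raise DefinitionError(f"indicator {ind_id}: no mitigation groups given")
        if kind == "condition_present" and not defn.trigger_conditions:
            raise DefinitionError(f"indicator {ind_id}: no trigger conditions given")
        if kind == "co_drug" and not defn.trigger_co_groups:
            raise DefinitionError(f"indicator {ind_id}: no co-drug groups given")
        if kind == "duration_gt" and not defn.duration_group:
            raise DefinitionError(f"indicator {ind_id}: no duration group given")
        defs[defn.id] = defn
    if not defs:
        raise DefinitionError("registry defines no indicators")
    return defs


# ----------------------------------------------------------------------
# evaluation helpers

def _therapy_events(bundle: EHRBundle, codes: frozenset) -> pd.DataFrame:
    """Dated therapy records (patient_id, date) whose drug code is in
    ``codes``; dates come from the linked consultation."""
    ther = bundle.therapy[bundle.therapy["drug_code"].isin(codes)]
    if ther.empty:
        return pd.DataFrame({"patient_id": [], "date": pd.Series(dtype="datetime64[ns]")})
    cons = bundle.consultations.set_index("consultation_id")
    return pd.DataFrame(
        {
            "patient_id": ther["consultation_id"].map(cons["patient_id"]).to_numpy(),
            "date": ther["consultation_id"].map(cons["date"]).to_numpy(),
        }
    )


def _group_codes(registry: CodelistRegistry, groups) -> frozenset:
    codes = frozenset()
    for g in groups:
        codes |= registry.drug_codes(g)
    return codes


def _has_event_in_window(index_df: pd.DataFrame, events: pd.DataFrame,
                         lo_days: int, hi_days: int) -> pd.Series:
    """For each index row, whether the patient has an event dated within
    [index + lo_days, index + hi_days] (inclusive). Indexed like index_df."""
    if index_df.empty or events.empty:
        return pd.Series(False, index=index_df.index)
    merged = index_df[["consultation_id", "patient_id", "date"]].merge(
        events, on="patient_id", how="inner", suffixes=("", "_ev")
    )
    delta = (merged["date_ev"] - merged["date"]).dt.days
    merged["hit"] = (delta >= lo_days) & (delta <= hi_days)
    hits = merged.groupby("consultation_id")["hit"].any()
    return index_df["consultation_id"].map(hits).eq(True)


def _condition_first_dates(bundle: EHRBundle, registry: CodelistRegistry,
                           condition: str) -> pd.Series:
    codes = registry.condition_codes(condition)
    clin = bundle.clinical[bundle.clinical["condition_code"].isin(codes)]
    if clin.empty:
        return pd.Series(dtype="datetime64[ns]")
    return clin.groupby("patient_id")["date"].min()


def find_index_events(bundle: EHRBundle, defn: IndicatorDefinition,
                      registry: CodelistRegistry | None = None) -> pd.DataFrame:
    """All face-to-face GP consultations satisfying the index predicate.
    Repeated consultations per patient are retained. Columns:
    consultation_id, patient_id, date, role, fy_year, age."""
    registry = registry or CodelistRegistry.default()
    cons = bundle.consultations
    f2f = cons[cons["staff_role"].isin(GP_ROLES) & (cons["mode"] == "face_to_face")]

    index_codes = _group_codes(registry, defn.index_drug_groups)
    with_rx = set(bundle.therapy.loc[
        bundle.therapy["drug_code"].isin(index_codes), "consultation_id"
    ])
    idx = f2f[f2f["consultation_id"].isin(with_rx)].copy()
    if idx.empty:
        return pd.DataFrame(
            columns=["consultation_id", "patient_id", "date", "role", "fy_year", "age"]
        )

    pts = bundle.patients.set_index("patient_id")
    idx["fy_year"] = fy_start_year(idx["date"])
    idx["age"] = idx["fy_year"] - idx["patient_id"].map(pts["birth_year"])
    if defn.min_age is not None:
        idx = idx[idx["age"] >= defn.min_age]

    for cond in defn.conditions:
        first = _condition_first_dates(bundle, registry, cond)
        have = idx["patient_id"].map(first)
        idx = idx[have.notna() & (have <= idx["date"])]
    for cond in defn.conditions_absent:
        first = _condition_first_dates(bundle, registry, cond)
        have = idx["patient_id"].map(first)
        idx = idx[~(have.notna() & (have <= idx["date"]))]

    if defn.co_drug_groups and not idx.empty:
        events = _therapy_events(bundle, _group_codes(registry, defn.co_drug_groups))
        covered = _has_event_in_window(idx, events, -defn.co_coverage_days, 0)
        idx = idx[covered.to_numpy()]

    out = idx.rename(columns={"staff_role": "role"})[
        ["consultation_id", "patient_id", "date", "role", "fy_year", "age"]
    ].reset_index(drop=True)
    return out


def _duration_flags(bundle: EHRBundle, registry: CodelistRegistry,
                    defn: IndicatorDefinition, index_df: pd.DataFrame) -> np.ndarray:
    """Continuous-exposure rule: prescriptions of the duration group are
    chained into episodes when successive gaps are <= grace_days; the flag
    fires when the episode ending at the index date spans > min_days."""
    events = _therapy_events(bundle, registry.drug_codes(defn.duration_group))
    by_patient = {
        pid: np.sort(grp["date"].to_numpy().astype("datetime64[D]").astype(int))
        for pid, grp in events.groupby("patient_id")
    }
    flags = np.zeros(len(index_df), dtype=bool)
    for k, (pid, date) in enumerate(zip(index_df["patient_id"], index_df["date"])):
        days = by_patient.get(pid)
        if days is None:
            continue
        d0 = np.datetime64(date, "D").astype(int)
        prior = np.unique(days[days <= d0])
        if len(prior) == 0 or prior[-1] != d0:
            continue
        start = d0
        for day in prior[::-1]:
            if start - day <= defn.grace_days:
                start = day
            else:
                break
        flags[k] = (d0 - start) > defn.min_days
    return flags


def evaluate_indicator(bundle: EHRBundle, defn: IndicatorDefinition,
                       registry: CodelistRegistry | None = None,
                       index_events: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-index-event trigger flags for one indicator.

    Returns the index events with a binary ``flag`` column: 1 when the risk
    condition holds and no mitigating prescription exists at the index
    consultation or within the mitigation lookback window."""
    registry = registry or CodelistRegistry.default()
    if index_events is None:
        index_events = find_index_events(bundle, defn, registry)
    out = index_events.copy()
    if out.empty:
        out["flag"] = pd.Series(dtype=int)
        return out

    if defn.trigger_kind == "no_mitigation":
        events = _therapy_events(bundle, _group_codes(registry, defn.mitigation_groups))
        mitigated = _has_event_in_window(out, events, -defn.lookback_days, 0)
        flags = ~mitigated.to_numpy()
    elif defn.trigger_kind == "condition_present":
        flags = np.zeros(len(out), dtype=bool)
        for cond in defn.trigger_conditions:
            first = out["patient_id"].map(_condition_first_dates(bundle, registry, cond))
            flags |= (first.notna() & (first <= out["date"])).to_numpy()
    elif defn.trigger_kind == "co_drug":
        events = _therapy_events(bundle, _group_codes(registry, defn.trigger_co_groups))
        flags = _has_event_in_window(out, events, -defn.coverage_days, 0).to_numpy()
    elif defn.trigger_kind == "duration_gt":
        flags = _duration_flags(bundle, registry, defn, out)
    else:  # pragma: no cover - load_registry rejects unknown kinds
        raise DefinitionError(f"unknown trigger kind {defn.trigger_kind!r}")

    out["flag"] = flags.astype(int)
    return out


def compute_results(flags: pd.DataFrame, indicator_id: str) -> list[IndicatorResult]:
    """Fold per-event flags into per-role numerator/denominator/rate.
    ``flags`` needs columns ``role`` and ``flag``."""
    results = []
    for role in GP_ROLES:
        sub = flags[flags["role"] == role] if not flags.empty else flags
        results.append(
            IndicatorResult(
                indicator=indicator_id,
                role=role,
                numerator=int(sub["flag"].sum()) if len(sub) else 0,
                denominator=int(len(sub)),
            )
        )
    return results


def results_table(bundle: EHRBundle, definitions: dict,
                  registry: CodelistRegistry | None = None) -> pd.DataFrame:
    """Evaluate every indicator and return the published-table shape:
    indicator, role, numerator, denominator, rate (percent, 1 dp)."""
    registry = registry or CodelistRegistry.default()
    rows = []
    for ind_id in sorted(definitions):
        flags = evaluate_indicator(bundle, definitions[ind_id], registry)
        for res in compute_results(flags, ind_id):
            rows.append(
                {
                    "indicator": res.indicator,
                    "role": res.role,
                    "numerator": res.numerator,
                    "denominator": res.denominator,
                    "rate": res.rate,
                }
            )
    return pd.DataFrame(rows)
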