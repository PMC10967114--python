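"""Independent brute-force oracles used to cross-check the vectorised
engines. Everything here is plain-Python row scanning over (index, event)
pairs — deliberately naive and kept free of the package's merge-based
implementations."""
from __future__ import annotations

import pandas as pd


def _day(ts) -> int:
    return pd.Timestamp(ts).to_datetime64().astype("datetime64[D]").astype(int)


class BundleView:
    """Plain-python row lists for oracle scans."""

    def __init__(self, bundle, registry):
        self.registry = registry
        self.patients = {r.patient_id: r for r in bundle.patients.itertuples()}
        self.consults = [r for r in bundle.consultations.itertuples()]
        self.by_id = {r.consultation_id: r for r in self.consults}
        self.therapy = [r for r in bundle.therapy.itertuples()]
        self.clinical = [r for r in bundle.clinical.itertuples()]
        self.hospital = [r for r in bundle.hospital.itertuples()]
        self.events = [r for r in bundle.consult_events.itertuples()]
        self.code_group = {}
        for grp in registry.drug_groups():
            for code in registry.drug_codes(grp):
                self.code_group[code] = grp
        self.code_cond = registry.code_to_condition()

    # ---- outcome flags -------------------------------------------------
    def revisit(self, cons_id, window=7):
        index = self.by_id[cons_id]
        d0 = _day(index.date)
        for c in self.consults:
            if c.patient_id == index.patient_id and 1 <= _day(c.date) - d0 <= window:
                return 1
        return 0

    def prescription(self, cons_id, codes):
        return int(any(t.consultation_id == cons_id and t.drug_code in codes
                       for t in self.therapy))

    def hospital_flags(self, cons_id, kind):
        index = self.by_id[cons_id]
        d0 = _day(index.date)
        same = later = 0
        for h in self.hospital:
            if h.patient_id != index.patient_id:
                continue
            if kind == "acsc_admission":
                if h.kind != "emergency_admission":
                    continue
                code = "" if pd.isna(h.icd10) else str(h.icd10)
                if not code or not any(code.startswith(p)
                                       for p in self.registry.acsc_prefixes):
                    continue
            elif h.kind != kind:
                continue
            delta = _day(h.date) - d0
            if delta == 0:
                same = 1
            elif 1 <= delta <= 7:
                later = 1
        return same, later

    def linked_event(self, cons_id, kind):
        return int(any(e.consultation_id == cons_id and e.kind == kind
                       for e in self.events))

    def all_outcome_flags(self, cons_id):
        reg = self.registry
        flags = {
            "revisit_7d": self.revisit(cons_id),
            "rx_antibiotic": self.prescription(cons_id, reg.drug_codes("antibiotic")),
            "rx_strong_opioid": self.prescription(cons_id, reg.drug_codes("strong_opioid")),
            "rx_hypnotic": self.prescription(cons_id, reg.drug_codes("hypnotic")),
            "referral": self.linked_event(cons_id, "referral"),
            "test": self.linked_event(cons_id, "test"),
        }
        for kind, prefix in (("ae_visit", "ae"), ("emergency_admission", "emerg"),
                             ("acsc_admission", "acsc")):
            same, later = self.hospital_flags(cons_id, kind)
            flags[f"{prefix}_same_day"] = same
            flags[f"{prefix}_1_7d"] = later
        return flags

    # ---- indicator evaluation -----------------------------------------
    def _rx_days(self, patient_id, groups):
        days = []
        for t in self.therapy:
            if self.code_group.get(t.drug_code) in groups:
                c = self.by_id[t.consultation_id]
                if c.patient_id == patient_id:
                    days.append(_day(c.date))
        return sorted(days)

    def _condition_ever(self, patient_id, condition, on_or_before_day):
        for r in self.clinical:
            if (r.patient_id == patient_id
                    and self.code_cond.get(r.condition_code) == condition
                    and _day(r.date) <= on_or_before_day):
                return True
        return False

    def is_index_event(self, cons, defn):
        if cons.staff_role not in ("permanent_gp", "locum_gp"):
            return False
        if cons.mode != "face_to_face":
            return False
        if not any(self.code_group.get(t.drug_code) in
                   self._expand(defn.index_drug_groups)
                   for t in self.therapy
                   if t.consultation_id == cons.consultation_id):
            return False
        d0 = _day(cons.date)
        if defn.min_age is not None:
            pat = self.patients[cons.patient_id]
            if pd.isna(pat.birth_year):
                return False
            ts = pd.Timestamp(cons.date)
            fy_year = ts.year if ts.month >= 4 else ts.year - 1
            if fy_year - pat.birth_year < defn.min_age:
                return False
        for cond in defn.conditions:
            if not self._condition_ever(cons.patient_id, cond, d0):
                return False
        for cond in defn.conditions_absent:
            if self._condition_ever(cons.patient_id, cond, d0):
                return False
        for lo, hi, groups in [(-defn.co_coverage_days, 0, defn.co_drug_groups)]:
            if groups and not any(
                d0 + lo <= d <= d0 + hi
                for d in self._rx_days(cons.patient_id, self._expand(groups))
            ):
                return False
        return True

    @staticmethod
    def _expand(groups):
        out = set()
        for g in groups:
            if g == "hypnotic":
                out |= {"benzodiazepine", "z_drug"}
            else:
                out.add(g)
        return out

    def indicator_flag(self, cons, defn):
        d0 = _day(cons.date)
        if defn.trigger_kind == "no_mitigation":
            days = self._rx_days(cons.patient_id, self._expand(defn.mitigation_groups))
            return int(not any(d0 - defn.lookback_days <= d <= d0 for d in days))
        if defn.trigger_kind == "condition_present":
            return int(any(self._condition_ever(cons.patient_id, c, d0)
                           for c in defn.trigger_conditions))
        if defn.trigger_kind == "co_drug":
            days = self._rx_days(cons.patient_id, self._expand(defn.trigger_co_groups))
            return int(any(d0 - defn.coverage_days <= d <= d0 for d in days))
        if defn.trigger_kind == "duration_gt":
            days = sorted(set(d for d in self._rx_days(cons.patient_id,
                                                       {defn.duration_group})
                              if d <= d0))
            if not days or days[-1] != d0:
                return 0
            start = d0
            for d in reversed(days):
                if start - d <= defn.grace_days:
                    start = d
                else:
                    break
            return int(d0 - start > defn.min_days)
        raise ValueError(defn.trigger_kind)

    def indicator_results(self, defn):
        """(consultation_id, role, flag) triples for every index event."""
        rows = []
        for cons in self.consults:
            if self.is_index_event(cons, defn):
                rows.append((cons.consultation_id, cons.staff_role,
                             self.indicator_flag(cons, defn)))
        return rows
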