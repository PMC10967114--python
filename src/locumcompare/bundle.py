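"""The EHR bundle: linked flat tables mirroring a CPRD-GOLD-style extract
(with HES-like hospital linkage), plus schema validation and directory I/O.

Tables
------
patients        patient_id, practice_id, region, gender (F/M, may be missing),
                birth_year (may be missing), death_date (optional),
                reg_start, reg_end (optional = still registered),
                imd_quintile (1..5), cm_score
practices       practice_id, region, list_size, rurality
consultations   consultation_id, patient_id, date,
                staff_role in {permanent_gp, locum_gp, other},
                mode in {face_to_face, telephone, online}
therapy         consultation_id, drug_code, group
clinical        patient_id, date, condition_code
hospital        patient_id, date, kind in {ae_visit, emergency_admission},
                icd10 (primary diagnosis; empty for A&E visits)
consult_events  consultation_id, kind in {test, referral}
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IntegrityError

STAFF_ROLES = ("permanent_gp", "locum_gp", "other")
GP_ROLES = ("permanent_gp", "locum_gp")
MODES = ("face_to_face", "telephone", "online")
HOSPITAL_KINDS = ("ae_visit", "emergency_admission")
EVENT_KINDS = ("test", "referral")

#: expected columns per table; date columns are parsed on read
TABLE_COLUMNS = {
    "patients": [
        "patient_id", "practice_id", "region", "gender", "birth_year",
        "death_date", "reg_start", "reg_end", "imd_quintile", "cm_score",
    ],
    "practices": ["practice_id", "region", "list_size", "rurality"],
    "consultations": ["consultation_id", "patient_id", "date", "staff_role", "mode"],
    "therapy": ["consultation_id", "drug_code", "group"],
    "clinical": ["patient_id", "date", "condition_code"],
    "hospital": ["patient_id", "date", "kind", "icd10"],
    "consult_events": ["consultation_id", "kind"],
}

DATE_COLUMNS = {
    "patients": ["death_date", "reg_start", "reg_end"],
    "consultations": ["date"],
    "clinical": ["date"],
    "hospital": ["date"],
}


def empty_table(name: str) -> pd.DataFrame:
    frame = pd.DataFrame({c: pd.Series(dtype=object) for c in TABLE_COLUMNS[name]})
    for col in DATE_COLUMNS.get(name, []):
        frame[col] = pd.Series(dtype="datetime64[ns]")
    return frame


@dataclass
class EHRBundle:
    """One linked set of flat tables; every pipeline stage consumes this."""

    patients: pd.DataFrame
    practices: pd.DataFrame
    consultations: pd.DataFrame
    therapy: pd.DataFrame
    clinical: pd.DataFrame
    hospital: pd.DataFrame
    consult_events: pd.DataFrame
    meta: dict = field(default_factory=dict)
    scenario_truth: pd.DataFrame | None = None

    @classmethod
    def empty(cls, meta=None) -> "EHRBundle":
        return cls(**{name: empty_table(name) for name in TABLE_COLUMNS},
                   meta=dict(meta or {}))

    def tables(self) -> dict:
        return {name: getattr(self, name) for name in TABLE_COLUMNS}

    def copy(self) -> "EHRBundle":
        return EHRBundle(
            **{k: v.copy() for k, v in self.tables().items()},
            meta=dict(self.meta),
            scenario_truth=None if self.scenario_truth is None else self.scenario_truth.copy(),
        )

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise IntegrityError on any schema or invariant violation."""
        problems = []
        for name, frame in self.tables().items():
            missing = set(TABLE_COLUMNS[name]) - set(frame.columns)
            if missing:
                problems.append(f"table {name!r}: missing column(s) {sorted(missing)}")
        if problems:
            raise IntegrityError("; ".join(problems))

        pts = self.patients.set_index("patient_id")
        if pts.index.has_duplicates:
            problems.append("patients: duplicate patient_id")
        if self.consultations["consultation_id"].duplicated().any():
            problems.append("consultations: duplicate consultation_id")
        known_patients = set(pts.index)
        for name in ("consultations", "clinical", "hospital"):
            bad = ~getattr(self, name)["patient_id"].isin(known_patients)
            if bad.any():
                problems.append(f"{name}: {int(bad.sum())} row(s) reference unknown patients")
        known_consults = set(self.consultations["consultation_id"])
        for name in ("therapy", "consult_events"):
            bad = ~getattr(self, name)["consultation_id"].isin(known_consults)
            if bad.any():
                problems.append(f"{name}: {int(bad.sum())} row(s) reference unknown consultations")

        quintile = pd.to_numeric(self.patients["imd_quintile"], errors="coerce")
        if not quintile.dropna().isin([1, 2, 3, 4, 5]).all():
            problems.append("patients: imd_quintile outside 1..5")
        if not self.consultations.empty:
            if not self.consultations["staff_role"].isin(STAFF_ROLES).all():
                problems.append("consultations: unknown staff_role")
            if not self.consultations["mode"].isin(MODES).all():
                problems.append("consultations: unknown mode")
        if not self.hospital.empty and not self.hospital["kind"].isin(HOSPITAL_KINDS).all():
            problems.append("hospital: unknown kind")

        # no record after its patient's death
        death = pts["death_date"]
        if death.notna().any():
            for name in ("consultations", "clinical", "hospital"):
                frame = getattr(self, name)
                if frame.empty:
                    continue
                d = frame["patient_id"].map(death)
                late = d.notna() & (frame["date"] > d)
                if late.any():
                    problems.append(f"{name}: {int(late.sum())} record(s) dated after death")
            # therapy dates live on their consultation
            if not self.therapy.empty:
                cd = self.consultations.set_index("consultation_id")
                t_pat = self.therapy["consultation_id"].map(cd["patient_id"])
                t_date = self.therapy["consultation_id"].map(cd["date"])
                d = t_pat.map(death)
                late = d.notna() & (t_date > d)
                if late.any():
                    problems.append(f"therapy: {int(late.sum())} record(s) dated after death")

        window = self.meta.get("window")
        if window:
            lo = pd.Timestamp(window["start"]) - pd.Timedelta(days=int(window.get("margin_days", 0)))
            hi = pd.Timestamp(window["end"])
            for name in ("consultations", "clinical", "hospital"):
                frame = getattr(self, name)
                if frame.empty:
                    continue
                out = (frame["date"] < lo) | (frame["date"] > hi)
                if out.any():
                    problems.append(f"{name}: {int(out.sum())} record(s) outside the study window")

        if problems:
            raise IntegrityError("; ".join(problems))


# ----------------------------------------------------------------------
# directory I/O (delimited flat files + manifest)

def _hashable_meta(meta: dict) -> str:
    return hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_bundle(bundle: EHRBundle, path) -> None:
    """Write one CSV per table plus ``manifest.json`` (row counts, meta hash)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "locumcompare-bundle/1",
        "tables": {},
        "meta": {k: str(v) if isinstance(v, pd.Timestamp) else v
                 for k, v in bundle.meta.items()},
    }
    tables = dict(bundle.tables())
    if bundle.scenario_truth is not None:
        tables["scenario_truth"] = bundle.scenario_truth
    for name, frame in tables.items():
        out = frame.copy()
        for col in DATE_COLUMNS.get(name, []):
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        out.to_csv(path / f"{name}.csv", index=False, lineterminator="\n")
        manifest["tables"][name] = int(len(frame))
    manifest["meta_hash"] = _hashable_meta(manifest["meta"])
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _read_table(path: Path, name: str) -> pd.DataFrame:
    file = path / f"{name}.csv"
    if not file.exists():
        raise IntegrityError(f"bundle at {path} is missing table {name!r}")
    frame = pd.read_csv(file, dtype=str, keep_default_na=False)
    missing = set(TABLE_COLUMNS[name]) - set(frame.columns)
    if missing:
        raise IntegrityError(f"table {name!r}: missing column(s) {sorted(missing)}")
    extra = set(frame.columns) - set(TABLE_COLUMNS[name])
    if extra:
        warnings.warn(f"table {name!r}: unknown column(s) {sorted(extra)} preserved")
    for col in DATE_COLUMNS.get(name, []):
        raw = frame[col].replace("", None)
        try:
            frame[col] = pd.to_datetime(raw, format="%Y-%m-%d")
        except (ValueError, TypeError) as exc:
            raise IntegrityError(f"table {name!r}, column {col!r}: date parse failure ({exc})")
    for col, kind in _NUMERIC_COLUMNS.get(name, {}).items():
        frame[col] = pd.to_numeric(frame[col].replace("", None), errors="coerce")
        if kind is int:
            # nullable ints survive the round trip as floats unless whole
            if frame[col].notna().all():
                frame[col] = frame[col].astype(np.int64)
    return frame


_NUMERIC_COLUMNS = {
    "patients": {"birth_year": float, "imd_quintile": int, "cm_score": float},
    "practices": {"list_size": int, "rurality": int},
}


def read_bundle(path) -> EHRBundle:
    path = Path(path)
    manifest_file = path / "manifest.json"
    if not manifest_file.exists():
        raise IntegrityError(f"no manifest.json in bundle directory {path}")
    with open(manifest_file) as fh:
        manifest = json.load(fh)
    tables = {name: _read_table(path, name) for name in TABLE_COLUMNS}
    truth = None
    if (path / "scenario_truth.csv").exists():
        truth = pd.read_csv(path / "scenario_truth.csv", dtype=str, keep_default_na=False)
    bundle = EHRBundle(**tables, meta=dict(manifest.get("meta", {})), scenario_truth=truth)
    for name, n in manifest.get("tables", {}).items():
        have = len(truth) if name == "scenario_truth" else len(tables.get(name, ()))
        if name in tables and have != n:
            raise IntegrityError(f"table {name!r}: manifest says {n} rows, file has {have}")
    return bundle
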