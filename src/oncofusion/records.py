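"""Patient-centered cohort records: data model, validation, JSON I/O.

A cohort is stored as a single JSON array with one object per patient,
merging all structured modalities (demographics, pathology, blood panel,
ICD codes, TMA immune-cell densities, event timeline).  All event fields
are day counts relative to the initial diagnosis (day 0).  Missing values
are encoded as JSON ``null``; an absent key is equivalent to null.

The machine-readable data dictionary shipped at
``oncofusion/data/data_dictionary.json`` documents every field, its type
and its admissible values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Any, Iterator

__all__ = [
    "PatientRecord",
    "Cohort",
    "CohortFormatError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "load_data_dictionary",
    "SEX_LEVELS",
    "SMOKING_LEVELS",
    "SITE_LEVELS",
    "GRADING_LEVELS",
    "PT_LEVELS",
    "PN_LEVELS",
    "TMA_KEYS",
]

SEX_LEVELS = ("male", "female")
SMOKING_LEVELS = ("never", "former", "current", "unknown")
SITE_LEVELS = ("oral_cavity", "oropharynx", "hypopharynx", "larynx", "cup")
GRADING_LEVELS = ("G1", "G2", "G3", "G4")
PT_LEVELS = ("pTis", "pT1", "pT2", "pT3", "pT4", "pT4a", "pT4b")
PN_LEVELS = ("pN0", "pN1", "pN2", "pN2a", "pN2b", "pN2c", "pN3")
TMA_KEYS = (
    "CD3_tumor_center",
    "CD3_invasion_front",
    "CD8_tumor_center",
    "CD8_invasion_front",
)

FLAG_FIELDS = (
    "lymphatic_invasion",
    "vascular_invasion",
    "perineural_invasion",
    "carcinoma_in_situ",
    "hpv_positive",
    "resection_margin_positive",
)

# Canonical key order for serialized records; write_cohort emits exactly this.
_KEY_ORDER = (
    "patient_id",
    "sex",
    "age_at_diagnosis",
    "smoking_status",
    "primary_site",
    "grading",
    "pt_stage",
    "pn_stage",
    *FLAG_FIELDS,
    "blood",
    "icd_codes",
    "tma_density",
    "recurrence_days",
    "death_days",
    "death_tumor_specific",
    "followup_days",
)


class CohortFormatError(ValueError):
    """The file is not a parseable JSON array of record objects."""


class CohortValidationError(ValueError):
    """A record violates the data dictionary; message names patient and field."""


@dataclass
class PatientRecord:
    """One patient's multimodal structured data plus event timeline."""

    patient_id: str
    sex: str
    age_at_diagnosis: int
    smoking_status: str
    primary_site: str
    followup_days: int
    grading: str | None = None
    pt_stage: str | None = None
    pn_stage: str | None = None
    lymphatic_invasion: bool | None = None
    vascular_invasion: bool | None = None
    perineural_invasion: bool | None = None
    carcinoma_in_situ: bool | None = None
    hpv_positive: bool | None = None
    resection_margin_positive: bool | None = None
    blood: dict[str, dict[str, Any]] = field(default_factory=dict)
    icd_codes: list[str] = field(default_factory=list)
    tma_density: dict[str, float | None] = field(default_factory=dict)
    recurrence_days: int | None = None
    death_days: int | None = None
    death_tumor_specific: bool | None = None

    def to_dict(self) -> dict[str, Any]:
        """Serializable mapping with keys in the canonical order."""
        raw = asdict(self)
        return {k: raw[k] for k in _KEY_ORDER}

    @classmethod
    def from_dict(cls, obj: dict[str, Any]) -> "PatientRecord":
        known = {k: obj[k] for k in _KEY_ORDER if k in obj}
        known.setdefault("blood", {})
        known.setdefault("icd_codes", [])
        known.setdefault("tma_density", {})
        if known.get("blood") is None:
            known["blood"] = {}
        if known.get("icd_codes") is None:
            known["icd_codes"] = []
        if known.get("tma_density") is None:
            known["tma_density"] = {}
        return cls(**known)


@dataclass
class Cohort:
    """Ordered collection of validated patient records (sorted by patient_id)."""

    records: list[PatientRecord]
    schema_version: str = "1.0"

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: r.patient_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    def subset(self, ids: list[str]) -> "Cohort":
        """New cohort restricted to the given patient IDs (order re-sorted)."""
        wanted = set(ids)
        missing = wanted - set(self.patient_ids)
        if missing:
            raise CohortValidationError(f"unknown patient ids: {sorted(missing)}")
        return Cohort([r for r in self.records if r.patient_id in wanted],
                      schema_version=self.schema_version)


def load_data_dictionary() -> dict[str, Any]:
    """The shipped machine-readable data dictionary."""
    text = resources.files("oncofusion.data").joinpath("data_dictionary.json").read_text()
    return json.loads(text)


def _err(pid: str, fieldname: str, msg: str) -> CohortValidationError:
    return CohortValidationError(f"patient {pid!r}, field {fieldname!r}: {msg}")


def _check_tristate(rec: PatientRecord, name: str) -> None:
    v = getattr(rec, name)
    if v is not None and not isinstance(v, bool):
        raise _err(rec.patient_id, name, f"expected true/false/null, got {v!r}")


def _check_day(rec: PatientRecord, name: str, required: bool = False) -> None:
    v = getattr(rec, name)
    if v is None:
        if required:
            raise _err(rec.patient_id, name, "required day count is missing")
        return
    if isinstance(v, bool) or not isinstance(v, int):
        raise _err(rec.patient_id, name, f"day count must be an integer, got {v!r}")
    if v < 0:
        raise _err(rec.patient_id, name, f"day count must be >= 0, got {v}")


def validate_record(rec: PatientRecord) -> None:
    """Raise :class:`CohortValidationError` on any domain violation."""
    pid = rec.patient_id
    if not isinstance(pid, str) or not pid:
        raise CohortValidationError(f"patient_id must be a non-empty string, got {pid!r}")
    if rec.sex not in SEX_LEVELS:
        raise _err(pid, "sex", f"{rec.sex!r} not in {SEX_LEVELS}")
    if isinstance(rec.age_at_diagnosis, bool) or not isinstance(rec.age_at_diagnosis, int) \
            or rec.age_at_diagnosis < 0:
        raise _err(pid, "age_at_diagnosis", f"expected integer >= 0, got {rec.age_at_diagnosis!r}")
    if rec.smoking_status not in SMOKING_LEVELS:
        raise _err(pid, "smoking_status", f"{rec.smoking_status!r} not in {SMOKING_LEVELS}")
    if rec.primary_site not in SITE_LEVELS:
        raise _err(pid, "primary_site", f"{rec.primary_site!r} not in {SITE_LEVELS}")
    if rec.grading is not None and rec.grading not in GRADING_LEVELS:
        raise _err(pid, "grading", f"{rec.grading!r} not in {GRADING_LEVELS}")
    if rec.pt_stage is not None and rec.pt_stage not in PT_LEVELS:
        raise _err(pid, "pt_stage", f"{rec.pt_stage!r} not in {PT_LEVELS}")
    if rec.pn_stage is not None and rec.pn_stage not in PN_LEVELS:
        raise _err(pid, "pn_stage", f"{rec.pn_stage!r} not in {PN_LEVELS}")
    for name in FLAG_FIELDS:
        _check_tristate(rec, name)
    for pname, entry in rec.blood.items():
        if entry is None:
            continue
        if not isinstance(entry, dict) or "value" not in entry:
            raise _err(pid, f"blood[{pname}]", "expected object with a 'value' key")
        val = entry["value"]
        if val is not None and not (isinstance(val, (int, float)) and math.isfinite(val)):
            raise _err(pid, f"blood[{pname}]", f"value must be finite, got {val!r}")
    if not isinstance(rec.icd_codes, list) or any(not isinstance(c, str) for c in rec.icd_codes):
        raise _err(pid, "icd_codes", "expected a list of strings")
    for key, dens in rec.tma_density.items():
        if key not in TMA_KEYS:
            raise _err(pid, f"tma_density[{key}]", f"unknown key, expected one of {TMA_KEYS}")
        if dens is not None and (not isinstance(dens, (int, float)) or not math.isfinite(dens) or dens < 0):
            raise _err(pid, f"tma_density[{key}]", f"density must be a finite float >= 0, got {dens!r}")
    _check_tristate(rec, "death_tumor_specific")
    _check_day(rec, "recurrence_days")
    _check_day(rec, "death_days")
    _check_day(rec, "followup_days", required=True)


def validate_cohort(cohort: Cohort) -> None:
    """Validate every record and cohort-level invariants (unique IDs)."""
    seen: set[str] = set()
    for rec in cohort.records:
        validate_record(rec)
        if rec.patient_id in seen:
            raise CohortValidationError(f"duplicate patient_id {rec.patient_id!r}")
        seen.add(rec.patient_id)


def read_cohort(path: str | Path) -> Cohort:
    """Read and validate a cohort from a JSON-array file.

    Unknown extra keys on a record are preserved in the file but ignored
    here; records are returned sorted by ``patient_id``.
    """
    try:
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise CohortFormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(payload, list):
        raise CohortFormatError(f"{path}: expected a JSON array of record objects")
    recs = []
    for i, obj in enumerate(payload):
        if not isinstance(obj, dict):
            raise CohortFormatError(f"{path}: entry {i} is not an object")
        recs.append(PatientRecord.from_dict(obj))
    cohort = Cohort(recs)
    validate_cohort(cohort)
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a validated cohort as a deterministic, bit-stable JSON array."""
    validate_cohort(cohort)
    objs = [r.to_dict() for r in cohort.records]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(objs, fh, indent=1, sort_keys=False, ensure_ascii=False)
        fh.write("\n")
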