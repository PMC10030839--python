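"""Patient and cohort data model.

A patient record carries age, sex, a deduplicated medication list (each
medication optionally annotated with daily dose in mg and treatment duration
in days) and a set of chronic-disease ids.  When a duration is not recorded it
defaults to 90 days at screening time, reflecting the working assumption that
chronic-care patients have been on their medications for at least three
months.

Cohorts round-trip through a flat CSV schema
(``patient_id,age_years,sex,medications,diseases`` with ``;``-joined
``drug_id[:dose_mg[:duration_days]]`` medication tokens) or an equivalent
JSON document.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "DEFAULT_DURATION_DAYS",
    "MedicationRecord",
    "Patient",
    "Cohort",
    "CohortError",
    "load_cohort",
    "write_cohort",
    "patient_flags",
]

#: Effective treatment duration assumed when none is recorded (~3 months).
DEFAULT_DURATION_DAYS = 90

POLYPHARMACY_MIN_DRUGS = 5
MULTIMORBIDITY_MIN_DISEASES = 2


class CohortError(ValueError):
    """Raised for malformed patient or cohort data."""


@dataclass(frozen=True)
class MedicationRecord:
    """One medication of a patient with optional dose and duration."""

    drug_id: str
    dose_mg_per_day: float | None = None
    duration_days: int | None = None

    def __post_init__(self) -> None:
        if self.dose_mg_per_day is not None and self.dose_mg_per_day < 0:
            raise CohortError(f"negative dose for {self.drug_id!r}")
        if self.duration_days is not None and self.duration_days < 0:
            raise CohortError(f"negative duration for {self.drug_id!r}")

    @property
    def effective_duration_days(self) -> int:
        """Recorded duration, or the 90-day default when absent."""
        return self.duration_days if self.duration_days is not None else DEFAULT_DURATION_DAYS


def _merge_optional(a, b):
    """Max of two optional numbers; None only when both are None (worst case)."""
    if a is None:
        return b
    if b is None:
        return a
    return max(a, b)


@dataclass(frozen=True)
class Patient:
    """A geriatric patient: age, sex, medications, chronic diseases.

    Construction normalises the medication list: duplicate ``drug_id`` entries
    collapse to one record keeping the maximum dose and duration, and
    medications are kept in sorted order so equal patients compare equal.
    Normalisation is idempotent.
    """

    patient_id: str
    age_years: int
    sex: str = "U"
    medications: tuple[MedicationRecord, ...] = ()
    diseases: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise CohortError(f"patient {self.patient_id!r}: negative age")
        if self.sex not in ("M", "F", "U"):
            raise CohortError(f"patient {self.patient_id!r}: sex must be M, F or U")
        merged: dict[str, MedicationRecord] = {}
        for rec in self.medications:
            prev = merged.get(rec.drug_id)
            if prev is None:
                merged[rec.drug_id] = rec
            else:
                merged[rec.drug_id] = MedicationRecord(
                    rec.drug_id,
                    _merge_optional(prev.dose_mg_per_day, rec.dose_mg_per_day),
                    _merge_optional(prev.duration_days, rec.duration_days),
                )
        object.__setattr__(
            self, "medications", tuple(merged[d] for d in sorted(merged))
        )
        object.__setattr__(self, "diseases", frozenset(self.diseases))

    @property
    def n_medications(self) -> int:
        return len(self.medications)

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)


def patient_flags(p: Patient) -> dict[str, bool]:
    """Polypharmacy (≥5 distinct drugs) and multimorbidity (≥2 chronic diseases)."""
    return {
        "polypharmacy": p.n_medications >= POLYPHARMACY_MIN_DRUGS,
        "multimorbidity": p.n_diseases >= MULTIMORBIDITY_MIN_DISEASES,
    }


@dataclass
class Cohort:
    """An ordered list of patients with unique ids."""

    patients: list[Patient] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.patients:
            if p.patient_id in seen:
                raise CohortError(f"duplicate patient_id {p.patient_id!r} in cohort")
            seen.add(p.patient_id)

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[Patient]:
        return iter(self.patients)


# ---------------------------------------------------------------------------
# Medication-token and file I/O
# ---------------------------------------------------------------------------


def parse_medication_token(token: str) -> MedicationRecord:
    """Parse ``drug_id[:dose_mg[:duration_days]]`` (empty parts allowed)."""
    parts = token.strip().split(":")
    if not parts[0] or len(parts) > 3:
        raise CohortError(f"malformed medication token {token!r}")
    try:
        dose = float(parts[1]) if len(parts) > 1 and parts[1] != "" else None
        duration = int(float(parts[2])) if len(parts) > 2 and parts[2] != "" else None
    except ValueError:
        raise CohortError(f"malformed medication token {token!r}") from None
    return MedicationRecord(parts[0], dose, duration)


def format_medication_token(rec: MedicationRecord) -> str:
    # repr gives the shortest exact decimal, so doses round-trip losslessly
    dose = "" if rec.dose_mg_per_day is None else repr(float(rec.dose_mg_per_day))
    duration = "" if rec.duration_days is None else str(rec.duration_days)
    if duration:
        return f"{rec.drug_id}:{dose}:{duration}"
    if dose:
        return f"{rec.drug_id}:{dose}"
    return rec.drug_id


def _split_list(cell: str) -> list[str]:
    return [tok for tok in (t.strip() for t in cell.split(";")) if tok]


def _patient_from_fields(
    patient_id: str, age: int, sex: str, med_tokens: Iterable[str], disease_ids: Iterable[str], row: int | None = None
) -> Patient:
    try:
        meds = tuple(parse_medication_token(tok) for tok in med_tokens)
        return Patient(str(patient_id), int(age), sex, meds, frozenset(disease_ids))
    except CohortError as exc:
        where = f" (row {row})" if row is not None else ""
        raise CohortError(f"{exc}{where}") from None


def load_cohort(path: str | Path) -> Cohort:
    """Read a cohort from CSV or JSON (by file extension).

    Patients are normalised on load; medications referencing drugs absent from
    a given knowledge base are retained here and reported as ``UNKNOWN_AGENT``
    at screening time.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"cohort file missing: {path}")
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        records = payload["patients"] if isinstance(payload, dict) else payload
        patients = [
            _patient_from_fields(
                rec["patient_id"],
                rec["age_years"],
                rec.get("sex", "U"),
                rec.get("medications", []),
                rec.get("diseases", []),
                row=i,
            )
            for i, rec in enumerate(records, start=1)
        ]
        return Cohort(patients)

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["patient_id", "age_years", "sex", "medications", "diseases"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortError(f"{path.name}: missing column(s) {', '.join(missing)}")
    patients = []
    for i, row in enumerate(df.itertuples(), start=1):
        try:
            age = int(float(row.age_years))
        except ValueError:
            raise CohortError(f"{path.name} row {i}: bad age {row.age_years!r}") from None
        patients.append(
            _patient_from_fields(
                row.patient_id, age, row.sex or "U",
                _split_list(row.medications), _split_list(row.diseases), row=i,
            )
        )
    return Cohort(patients)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV or JSON (by file extension); inverse of :func:`load_cohort`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        payload = {
            "patients": [
                {
                    "patient_id": p.patient_id,
                    "age_years": p.age_years,
                    "sex": p.sex,
                    "medications": [format_medication_token(m) for m in p.medications],
                    "diseases": sorted(p.diseases),
                }
                for p in cohort
            ]
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    rows = [
        {
            "patient_id": p.patient_id,
            "age_years": p.age_years,
            "sex": p.sex,
            "medications": ";".join(format_medication_token(m) for m in p.medications),
            "diseases": ";".join(sorted(p.diseases)),
        }
        for p in cohort
    ]
    pd.DataFrame(
        rows, columns=["patient_id", "age_years", "sex", "medications", "diseases"]
    ).to_csv(path, index=False)
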