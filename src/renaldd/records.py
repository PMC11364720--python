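"""Patient-level domain types and delimited-text (CSV) serialization.

One :class:`PatientRecord` is one emergency-department presentation with a
D-dimer measurement and a CT-angiography outcome.  Records are immutable and
validated at construction time; the CSV reader re-validates every row and
reports row-numbered errors.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class RenalStratum(str, Enum):
    """Renal-function bands on CKD-EPI eGFR (ml/min)."""

    GTE60 = "gte60"
    S30_59 = "s30_59"
    LT30 = "lt30"


class WellsClass(str, Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


class PELocation(str, Enum):
    PERIPHERAL_SUBSEGMENTAL = "peripheral_subsegmental"
    SEGMENTAL = "segmental"
    PARACENTRAL = "paracentral"
    CENTRAL = "central"


WELLS_ITEM_NAMES = (
    "clinical_dvt_signs",
    "pe_most_likely",
    "tachycardia_gt100",
    "surgery_or_immobilization",
    "previous_pe_dvt",
    "hemoptysis",
    "malignancy",
)


@dataclass(frozen=True)
class WellsItems:
    """The seven binary items of the two-level Wells rule."""

    clinical_dvt_signs: bool = False
    pe_most_likely: bool = False
    tachycardia_gt100: bool = False
    surgery_or_immobilization: bool = False
    previous_pe_dvt: bool = False
    hemoptysis: bool = False
    malignancy: bool = False

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, name) for name in WELLS_ITEM_NAMES)


@dataclass(frozen=True)
class PatientRecord:
    """One ED presentation: demographics, labs, Wells items, CTA outcome.

    Units: creatinine µmol/l, CRP mg/l, D-dimer µg/l, age in whole years.
    ``pe`` is the CTA-confirmed pulmonary-embolism reference standard.
    """

    id: str
    age: int
    sex: Sex
    creatinine: float
    crp: float
    ddimer: float
    wells_items: WellsItems
    pe: bool
    black: bool = False
    pregnancy_perinatal: bool = False
    anticoagulated: bool = False
    pe_location: Optional[PELocation] = None

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValueError(f"record {self.id!r}: age must be >= 18, got {self.age}")
        if not self.creatinine > 0:
            raise ValueError(
                f"record {self.id!r}: creatinine must be > 0, got {self.creatinine}"
            )
        if self.crp < 0:
            raise ValueError(f"record {self.id!r}: crp must be >= 0, got {self.crp}")
        if not self.ddimer > 0:
            raise ValueError(
                f"record {self.id!r}: ddimer must be > 0, got {self.ddimer}"
            )
        if self.pe_location is not None and not self.pe:
            raise ValueError(
                f"record {self.id!r}: pe_location set but pe is false"
            )
        if self.pregnancy_perinatal and self.sex is not Sex.FEMALE:
            raise ValueError(
                f"record {self.id!r}: pregnancy_perinatal requires sex=female"
            )

    @property
    def malignancy(self) -> bool:
        """Active malignancy; carried by the corresponding Wells item."""
        return self.wells_items.malignancy


CSV_COLUMNS = (
    "id",
    "age",
    "sex",
    "black",
    "creatinine",
    "crp",
    "ddimer",
    *WELLS_ITEM_NAMES,
    "pregnancy_perinatal",
    "anticoagulated",
    "pe",
    "pe_location",
)

_BOOL_COLUMNS = frozenset(
    (*WELLS_ITEM_NAMES, "black", "pregnancy_perinatal", "anticoagulated", "pe")
)


def _format_bool(value: bool) -> str:
    return "1" if value else "0"


def _parse_bool(text: str, column: str) -> bool:
    if text == "1":
        return True
    if text == "0":
        return False
    raise ValueError(f"column {column!r}: expected 0/1, got {text!r}")


def write_cohort_csv(path, records: Iterable[PatientRecord]) -> None:
    """Write records as UTF-8 CSV with a header row, booleans as 0/1."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            row = [
                rec.id,
                rec.age,
                rec.sex.value,
                _format_bool(rec.black),
                repr(rec.creatinine),
                repr(rec.crp),
                repr(rec.ddimer),
                *(_format_bool(v) for v in rec.wells_items.as_tuple()),
                _format_bool(rec.pregnancy_perinatal),
                _format_bool(rec.anticoagulated),
                _format_bool(rec.pe),
                rec.pe_location.value if rec.pe_location is not None else "",
            ]
            writer.writerow(row)


class CohortReadError(ValueError):
    """Raised when a cohort CSV fails validation; message carries row numbers."""


def read_cohort_csv(path, drop_anticoagulated: bool = False) -> list[PatientRecord]:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path
        CSV file produced by :func:`write_cohort_csv` (or hand-built with
        the same header).
    drop_anticoagulated
        If true, rows with ``anticoagulated == 1`` are silently filtered
        out (the study-exclusion use case).

    Raises
    ------
    CohortReadError
        On a missing/extra header column or any invalid row; the message
        names the 1-based data row number.
    """
    records: list[PatientRecord] = []
    errors: list[str] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        header = tuple(reader.fieldnames or ())
        if header != CSV_COLUMNS:
            raise CohortReadError(
                f"unexpected header: got {header}, expected {CSV_COLUMNS}"
            )
        for row_no, row in enumerate(reader, start=1):
            try:
                records.append(_record_from_row(row))
            except (ValueError, KeyError) as exc:
                errors.append(f"row {row_no}: {exc}")
    if errors:
        raise CohortReadError("; ".join(errors))
    if drop_anticoagulated:
        records = [r for r in records if not r.anticoagulated]
    return records


def _record_from_row(row: dict) -> PatientRecord:
    bools = {col: _parse_bool(row[col], col) for col in _BOOL_COLUMNS}
    loc_text = row["pe_location"]
    pe_location = PELocation(loc_text) if loc_text else None
    return PatientRecord(
        id=row["id"],
        age=int(row["age"]),
        sex=Sex(row["sex"]),
        black=bools["black"],
        creatinine=float(row["creatinine"]),
        crp=float(row["crp"]),
        ddimer=float(row["ddimer"]),
        wells_items=WellsItems(**{k: bools[k] for k in WELLS_ITEM_NAMES}),
        pregnancy_perinatal=bools["pregnancy_perinatal"],
        anticoagulated=bools["anticoagulated"],
        pe=bools["pe"],
        pe_location=pe_location,
    )
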