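"""Deterministic clinical calculators.

CKD-EPI eGFR from serum creatinine, renal-function strata, the two-level
Wells score with its risk classes, the YEARS rule-out check, and the
conventional age-adjusted D-dimer cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .records import (
    PatientRecord,
    PELocation,
    RenalStratum,
    Sex,
    WellsClass,
    WellsItems,
)

#: µmol/l per mg/dl for creatinine.
CREATININE_UMOLL_PER_MGDL = 88.42

#: Wells item weights for the two-level rule, in record field order.
WELLS_WEIGHTS = {
    "clinical_dvt_signs": 3.0,
    "pe_most_likely": 3.0,
    "tachycardia_gt100": 1.5,
    "surgery_or_immobilization": 1.5,
    "previous_pe_dvt": 1.5,
    "hemoptysis": 1.0,
    "malignancy": 1.0,
}

#: Wells score below which a patient counts as low-to-moderate pre-test
#: probability (D-dimer-first workup).
WELLS_HIGH_THRESHOLD = 6.5

YEARS_ITEM_NAMES = ("clinical_dvt_signs", "hemoptysis", "pe_most_likely")


def ckd_epi_egfr(
    creatinine_umol_l: Union[float, np.ndarray],
    age: Union[float, np.ndarray],
    sex: Union[Sex, np.ndarray],
    black: Union[bool, np.ndarray] = False,
) -> Union[float, np.ndarray]:
    """CKD-EPI estimated glomerular filtration rate, ml/min, unrounded.

    ``eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.209 · 0.993^age``,
    with Scr in mg/dl (input creatinine is µmol/l and divided by 88.42),
    κ = 0.7 / 0.9 and α = −0.329 / −0.411 for female / male, times 1.018
    if female and 1.159 if black.

    Accepts scalars or numpy arrays (``sex`` as a boolean female mask in
    the array case).  No body-surface-area rescaling is applied.
    """
    scalar = np.isscalar(creatinine_umol_l) or np.ndim(creatinine_umol_l) == 0
    creat = np.asarray(creatinine_umol_l, dtype=float)
    age_arr = np.asarray(age, dtype=float)
    if isinstance(sex, Sex):
        female = np.asarray(sex is Sex.FEMALE)
    else:
        female = np.asarray(sex, dtype=bool)
    black_arr = np.asarray(black, dtype=bool)

    if np.any(creat <= 0):
        raise ValueError("creatinine must be > 0")
    if np.any(age_arr < 18):
        raise ValueError("age must be >= 18")

    scr = creat / CREATININE_UMOLL_PER_MGDL
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    ratio = scr / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993 ** age_arr
    )
    egfr = egfr * np.where(female, 1.018, 1.0) * np.where(black_arr, 1.159, 1.0)
    return float(egfr) if scalar else egfr


def classify_renal_stratum(egfr: float) -> RenalStratum:
    """Band an eGFR value: ≥60, 30–59, <30 ml/min (boundaries 60 and 30
    belong to the upper band)."""
    if not egfr > 0:
        raise ValueError(f"egfr must be > 0, got {egfr}")
    if egfr >= 60.0:
        return RenalStratum.GTE60
    if egfr >= 30.0:
        return RenalStratum.S30_59
    return RenalStratum.LT30


def wells_score(items: WellsItems) -> float:
    """Two-level Wells score: 3/3/1.5/1.5/1.5/1/1 weights, range 0–12.5."""
    return sum(
        weight
        for name, weight in WELLS_WEIGHTS.items()
        if getattr(items, name)
    )


def wells_class(score: float) -> WellsClass:
    """Risk class: low < 2, moderate 2–6, high > 6."""
    if score < 2.0:
        return WellsClass.LOW
    if score <= 6.0:
        return WellsClass.MODERATE
    return WellsClass.HIGH


def years_item_count(items: WellsItems) -> int:
    """Number of YEARS items present (DVT signs, hemoptysis, PE most likely)."""
    return sum(1 for name in YEARS_ITEM_NAMES if getattr(items, name))


def years_ruled_out(items: WellsItems, ddimer: float) -> bool:
    """YEARS rule-out: no items and D-dimer < 1000 µg/l, or ≥1 item and
    D-dimer < 500 µg/l (strict inequalities)."""
    if not ddimer > 0:
        raise ValueError("ddimer must be > 0")
    n_items = years_item_count(items)
    limit = 1000.0 if n_items == 0 else 500.0
    return ddimer < limit


def age_adjusted_cutoff(age: float) -> float:
    """Conventional age-adjusted D-dimer cutoff: 500 µg/l up to age 50,
    age × 10 µg/l above."""
    if age < 18:
        raise ValueError("age must be >= 18")
    return 500.0 if age <= 50 else age * 10.0


@dataclass(frozen=True)
class AnnotatedRecord(PatientRecord):
    """A :class:`PatientRecord` plus all derived clinical quantities."""

    egfr: float = 0.0
    renal_stratum: RenalStratum = RenalStratum.GTE60
    wells_score: float = 0.0
    wells_class: WellsClass = WellsClass.LOW
    wells_lt_6_5: bool = True
    years_items: int = 0
    age_adjusted_cutoff: float = 500.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.egfr > 0:
            raise ValueError(f"record {self.id!r}: egfr must be > 0")


def annotate(record: PatientRecord) -> AnnotatedRecord:
    """Compute eGFR, renal stratum, Wells score/class and YEARS items for
    one record."""
    egfr = ckd_epi_egfr(record.creatinine, record.age, record.sex, record.black)
    score = wells_score(record.wells_items)
    return AnnotatedRecord(
        **_record_kwargs(record),
        egfr=egfr,
        renal_stratum=classify_renal_stratum(egfr),
        wells_score=score,
        wells_class=wells_class(score),
        wells_lt_6_5=score < WELLS_HIGH_THRESHOLD,
        years_items=years_item_count(record.wells_items),
        age_adjusted_cutoff=age_adjusted_cutoff(record.age),
    )


def _record_kwargs(record: PatientRecord) -> dict:
    return {
        "id": record.id,
        "age": record.age,
        "sex": record.sex,
        "black": record.black,
        "creatinine": record.creatinine,
        "crp": record.crp,
        "ddimer": record.ddimer,
        "wells_items": record.wells_items,
        "pregnancy_perinatal": record.pregnancy_perinatal,
        "anticoagulated": record.anticoagulated,
        "pe": record.pe,
        "pe_location": record.pe_location,
    }


def annotate_all(records: Sequence[PatientRecord]) -> list[AnnotatedRecord]:
    return [annotate(r) for r in records]
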