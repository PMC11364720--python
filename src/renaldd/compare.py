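"""Strategy comparison: net reclassification improvement, avoided-CTA cost
accounting, and the D-dimer determinant regressions.

A *strategy* decides, per annotated record, whether a CTA is indicated
(test positive) or the patient is ruled out (test negative).  Strategies
can be built programmatically or parsed from a small JSON spec:

    {"type": "fixed", "cutoff": 500}
    {"type": "age_adjusted"}
    {"type": "renal_adjusted", "cutoffs": {"gte60": 500, "s30_59": 1480, "lt30": 1351}}
    {"type": "refer_all"}
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import RenalStratum, Sex
from .scores import AnnotatedRecord, age_adjusted_cutoff


# ---------------------------------------------------------------------------
# Strategies
# ---------------------------------------------------------------------------

class Strategy:
    """Dichotomous CTA-vs-rule-out decision rule."""

    label = "strategy"

    def is_positive(self, record: AnnotatedRecord) -> bool:
        raise NotImplementedError

    def to_spec(self) -> dict:
        raise NotImplementedError


@dataclass(frozen=True)
class FixedCutoff(Strategy):
    cutoff: float
    label: str = "fixed"

    def is_positive(self, record: AnnotatedRecord) -> bool:
        return record.ddimer >= self.cutoff

    def to_spec(self) -> dict:
        return {"type": "fixed", "cutoff": self.cutoff}


@dataclass(frozen=True)
class AgeAdjusted(Strategy):
    """Positive iff D-dimer ≥ the record's age-adjusted cutoff
    (500 µg/l up to age 50, age × 10 above)."""

    label: str = "age_adjusted"

    def is_positive(self, record: AnnotatedRecord) -> bool:
        return record.ddimer >= age_adjusted_cutoff(record.age)

    def to_spec(self) -> dict:
        return {"type": "age_adjusted"}


@dataclass(frozen=True)
class RenalAdjusted(Strategy):
    """Per-renal-stratum fixed cutoffs (µg/l)."""

    gte60: float
    s30_59: float
    lt30: float
    label: str = "renal_adjusted"

    def is_positive(self, record: AnnotatedRecord) -> bool:
        cutoff = {
            RenalStratum.GTE60: self.gte60,
            RenalStratum.S30_59: self.s30_59,
            RenalStratum.LT30: self.lt30,
        }[record.renal_stratum]
        return record.ddimer >= cutoff

    def to_spec(self) -> dict:
        return {
            "type": "renal_adjusted",
            "cutoffs": {"gte60": self.gte60, "s30_59": self.s30_59, "lt30": self.lt30},
        }


@dataclass(frozen=True)
class ReferAll(Strategy):
    """Every patient gets a CTA (no rule-out)."""

    label: str = "refer_all"

    def is_positive(self, record: AnnotatedRecord) -> bool:
        return True

    def to_spec(self) -> dict:
        return {"type": "refer_all"}


def strategy_from_spec(spec: dict) -> Strategy:
    kind = spec.get("type")
    if kind == "fixed":
        return FixedCutoff(cutoff=float(spec["cutoff"]))
    if kind == "age_adjusted":
        return AgeAdjusted()
    if kind == "renal_adjusted":
        cutoffs = spec["cutoffs"]
        return RenalAdjusted(
            gte60=float(cutoffs["gte60"]),
            s30_59=float(cutoffs["s30_59"]),
            lt30=float(cutoffs["lt30"]),
        )
    if kind == "refer_all":
        return ReferAll()
    raise ValueError(f"unknown strategy type {kind!r}")


# ---------------------------------------------------------------------------
# Net reclassification improvement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NRIResult:
    """Two-category NRI between an old and a new classification rule.

    ``up`` means reclassified negative→positive under the new rule, ``down``
    positive→negative.  A component is None when its denominator class is
    absent; nri is None whenever either component is.
    """

    nri: Optional[float]
    event_component: Optional[float]
    nonevent_component: Optional[float]
    n_events: int
    n_nonevents: int


def nri(
    records: Sequence[AnnotatedRecord],
    classifier_old: Strategy,
    classifier_new: Strategy,
) -> NRIResult:
    """event component [P(up|PE) − P(down|PE)] plus nonevent component
    [P(down|no PE) − P(up|no PE)]."""
    up_ev = down_ev = up_ne = down_ne = 0
    n_ev = n_ne = 0
    for rec in records:
        old_pos = classifier_old.is_positive(rec)
        new_pos = classifier_new.is_positive(rec)
        up = new_pos and not old_pos
        down = old_pos and not new_pos
        if rec.pe:
            n_ev += 1
            up_ev += up
            down_ev += down
        else:
            n_ne += 1
            up_ne += up
            down_ne += down
    ev = (up_ev - down_ev) / n_ev if n_ev else None
    ne = (down_ne - up_ne) / n_ne if n_ne else None
    total = ev + ne if ev is not None and ne is not None else None
    return NRIResult(
        nri=total,
        event_component=ev,
        nonevent_component=ne,
        n_events=n_ev,
        n_nonevents=n_ne,
    )


# ---------------------------------------------------------------------------
# Avoided-CTA cost accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CostResult:
    stratum_label: str
    cta_negative_old: int
    cta_negative_new: int
    avoided: int
    unit_cost: float
    total_saved: float
    missed_pe: int


def cost_saved(
    records: Sequence[AnnotatedRecord],
    strategy_old: Strategy,
    strategy_new: Strategy,
    unit_cost: float,
    stratum_label: str = "",
) -> CostResult:
    """Negative CTAs (scan performed, no PE) under each strategy, scans
    avoided by switching, money saved, and PE cases the new strategy would
    rule out.

    Callers restrict ``records`` to the intended population (typically one
    renal stratum with Wells score < 6.5).
    """
    if unit_cost < 0:
        raise ValueError("unit_cost must be >= 0")
    neg_old = neg_new = missed = 0
    for rec in records:
        old_pos = strategy_old.is_positive(rec)
        new_pos = strategy_new.is_positive(rec)
        if not rec.pe:
            neg_old += old_pos
            neg_new += new_pos
        elif not new_pos:
            missed += 1
    avoided = neg_old - neg_new
    return CostResult(
        stratum_label=stratum_label,
        cta_negative_old=neg_old,
        cta_negative_new=neg_new,
        avoided=avoided,
        unit_cost=unit_cost,
        total_saved=avoided * unit_cost,
        missed_pe=missed,
    )


# ---------------------------------------------------------------------------
# Regression / correlation on D-dimer determinants
# ---------------------------------------------------------------------------

REGRESSION_COVARIATES = (
    "intercept",
    "age",
    "female",
    "pe",
    "malignancy",
    "pregnancy_perinatal",
    "ln_egfr",
    "ln_crp",
)


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


def _design_matrix(
    records: Sequence[AnnotatedRecord], crp_floor: float
) -> tuple[np.ndarray, np.ndarray]:
    n = len(records)
    x = np.empty((n, len(REGRESSION_COVARIATES)), dtype=float)
    y = np.empty(n, dtype=float)
    for i, rec in enumerate(records):
        x[i] = (
            1.0,
            float(rec.age),
            float(rec.sex is Sex.FEMALE),
            float(rec.pe),
            float(rec.malignancy),
            float(rec.pregnancy_perinatal),
            math.log(rec.egfr),
            math.log(max(rec.crp, crp_floor)),
        )
        y[i] = math.log(rec.ddimer)
    return x, y


def fit_lnddimer_regression(
    records: Sequence[AnnotatedRecord],
    crp_floor: float = 1.0,
    robust: bool = False,
) -> pd.DataFrame:
    """OLS of ln(D-dimer) on age, sex, PE, malignancy, pregnancy/perinatal,
    ln(eGFR) and ln(CRP), with intercept.

    Returns a DataFrame indexed by covariate name with columns
    ``estimate``, ``se``, ``p_value`` (classical errors by default, HC1 when
    ``robust``).  CRP values below ``crp_floor`` are floored before the log.
    """
    import statsmodels.api as sm

    if len(records) <= len(REGRESSION_COVARIATES):
        raise ValueError("need more records than covariates")
    x, y = _design_matrix(records, crp_floor)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify offending columns via the R factor of a pivoted QR
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        bad = [
            REGRESSION_COVARIATES[j]
            for j in range(x.shape[1])
            if diag[j] <= tol
        ]
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {x.shape[1]}; "
            f"collinear columns: {bad or 'undetermined'}"
        )
    model = sm.OLS(y, x)
    fit = model.fit(cov_type="HC1") if robust else model.fit()
    return pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "p_value": fit.pvalues,
        },
        index=list(REGRESSION_COVARIATES),
    )


def univariate_r(
    records: Sequence[AnnotatedRecord],
    x_field: str,
    y_field: str,
    log_x: bool = False,
    log_y: bool = False,
) -> tuple[float, float]:
    """Pearson correlation (R, p) between two record fields, with optional
    natural-log transforms; the p-value is the two-sided t-test."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    x = np.array([getattr(r, x_field) for r in records], dtype=float)
    y = np.array([getattr(r, y_field) for r in records], dtype=float)
    if log_x:
        if np.any(x <= 0):
            raise ValueError(f"log of non-positive {x_field}")
        x = np.log(x)
    if log_y:
        if np.any(y <= 0):
            raise ValueError(f"log of non-positive {y_field}")
        y = np.log(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
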