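"""Diagnostic test performance: 2×2 tables, standard-equation metrics with
confidence intervals, empirical AUC, and 2×2 odds ratios.

Conventions: test positive ⇔ D-dimer ≥ cutoff (the boundary value is
positive), condition positive ⇔ CTA-confirmed PE.  Ratios with a zero
denominator are reported as an explicit undefined marker
(:class:`Estimate` with ``value=None``), never silently as 0 or NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .scores import AnnotatedRecord

Z_95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class Estimate:
    """A point estimate with an optional two-sided 95% CI.

    ``value is None`` marks an undefined quantity (zero denominator);
    ``ci is None`` marks a defined value whose interval is unavailable.
    """

    value: Optional[float]
    ci: Optional[tuple] = None

    @property
    def defined(self) -> bool:
        return self.value is not None

    def __format__(self, spec: str) -> str:
        if self.value is None:
            return "undefined"
        return format(self.value, spec)


@dataclass(frozen=True)
class ConfusionTable:
    """2×2 counts of (D-dimer ≥ cutoff) against CTA-confirmed PE."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsSet:
    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    accuracy: Estimate
    plr: Estimate
    nlr: Estimate


def confusion_at_cutoff(
    records: Sequence[AnnotatedRecord], cutoff: float
) -> ConfusionTable:
    """Count the 2×2 table for the rule "positive iff ddimer ≥ cutoff"."""
    if not records:
        raise ValueError("records must be non-empty")
    if not cutoff > 0:
        raise ValueError("cutoff must be > 0")
    tp = fp = tn = fn = 0
    for rec in records:
        positive = rec.ddimer >= cutoff
        if rec.pe:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    return ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn)


def _proportion(count: int, nobs: int, ci_method: str) -> Estimate:
    if nobs == 0:
        return Estimate(None)
    method = {"wilson": "wilson", "clopper_pearson": "beta"}[ci_method]
    low, high = proportion_confint(count, nobs, alpha=0.05, method=method)
    low = 0.0 if count == 0 else max(0.0, float(low))
    high = 1.0 if count == nobs else min(1.0, float(high))
    return Estimate(count / nobs, (low, high))


def _plr(t: ConfusionTable, ci_method: str) -> Estimate:
    """sens/(1−spec); log-method CI, defined only with all four relevant
    cells positive."""
    if t.tp + t.fn == 0 or t.fp + t.tn == 0:
        return Estimate(None)
    sens = t.tp / (t.tp + t.fn)
    spec = t.tn / (t.fp + t.tn)
    if spec == 1.0:
        return Estimate(None)  # zero false positives: PLR diverges
    value = sens / (1.0 - spec)
    if t.tp == 0 or t.fp == 0:
        return Estimate(value)
    se = math.sqrt(
        1 / t.tp - 1 / (t.tp + t.fn) + 1 / t.fp - 1 / (t.fp + t.tn)
    )
    return Estimate(
        value, (value * math.exp(-Z_95 * se), value * math.exp(Z_95 * se))
    )


def _nlr(t: ConfusionTable, ci_method: str) -> Estimate:
    """(1−sens)/spec; log-method CI; 0 exactly when fn == 0."""
    if t.tp + t.fn == 0 or t.fp + t.tn == 0:
        return Estimate(None)
    sens = t.tp / (t.tp + t.fn)
    spec = t.tn / (t.fp + t.tn)
    if spec == 0.0:
        return Estimate(None)
    value = (1.0 - sens) / spec
    if t.fn == 0 or t.tn == 0:
        return Estimate(value)
    se = math.sqrt(
        1 / t.fn - 1 / (t.tp + t.fn) + 1 / t.tn - 1 / (t.fp + t.tn)
    )
    return Estimate(
        value, (value * math.exp(-Z_95 * se), value * math.exp(Z_95 * se))
    )


def metrics(table: ConfusionTable, ci_method: str = "wilson") -> MetricsSet:
    """Standard-equation metrics with 95% CIs.

    ``ci_method`` is ``"wilson"`` (default) or ``"clopper_pearson"`` for
    the proportion intervals; likelihood-ratio CIs use the log method.
    """
    if table.n == 0:
        raise ValueError("empty confusion table")
    if ci_method not in ("wilson", "clopper_pearson"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return MetricsSet(
        sensitivity=_proportion(table.tp, table.tp + table.fn, ci_method),
        specificity=_proportion(table.tn, table.tn + table.fp, ci_method),
        ppv=_proportion(table.tp, table.tp + table.fp, ci_method),
        npv=_proportion(table.tn, table.tn + table.fn, ci_method),
        accuracy=_proportion(table.tp + table.tn, table.n, ci_method),
        plr=_plr(table, ci_method),
        nlr=_nlr(table, ci_method),
    )


def empirical_auc(records: Sequence[AnnotatedRecord]) -> Estimate:
    """AUC of D-dimer as a continuous score for PE.

    Computed as the Mann–Whitney probability P(ddimer_PE > ddimer_noPE)
    with ties counted 1/2; Hanley–McNeil standard error for the 95% CI
    (clipped to [0, 1]).
    """
    scores = np.array([r.ddimer for r in records], dtype=float)
    labels = np.array([r.pe for r in records], dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("empirical_auc needs both PE and non-PE records")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    se = math.sqrt(max(var, 0.0))
    return Estimate(
        float(auc),
        (max(0.0, auc - Z_95 * se), min(1.0, auc + Z_95 * se)),
    )


@dataclass(frozen=True)
class OddsRatioResult:
    value: float
    ci: tuple
    p_value: float
    corrected: bool  # Haldane–Anscombe 0.5 applied to a zero cell


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> OddsRatioResult:
    """Odds ratio (a·d)/(b·c) with Wald log-scale 95% CI.

    A 0.5 continuity correction is added to every cell iff any cell is
    zero (Haldane–Anscombe); the p-value is Fisher's exact on the
    uncorrected counts.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0:
            raise ValueError(f"count {name} must be >= 0")
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected else (a, b, c, d)
    )
    value = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci = (value * math.exp(-Z_95 * se), value * math.exp(Z_95 * se))
    _, p = stats.fisher_exact([[a, b], [c, d]])
    return OddsRatioResult(value=value, ci=ci, p_value=float(p), corrected=corrected)
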