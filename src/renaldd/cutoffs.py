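"""NPV-constrained D-dimer cutoff derivation.

The rule-out rule is "negative iff ddimer < cutoff".  Within a stratum the
candidate cutoffs are exactly the observed unique D-dimer values (NPV is a
step function changing only there), and the derivation returns the largest
candidate whose point-estimate NPV meets the target — maximizing the number
of rule-outs subject to the safety constraint.  Candidates with zero
negatives have undefined NPV and are infeasible by definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .metrics import ConfusionTable, MetricsSet, confusion_at_cutoff, metrics
from .scores import AnnotatedRecord


@dataclass(frozen=True)
class CutoffResult:
    stratum_label: str
    target_npv: float
    cutoff: Optional[float]
    metrics_at_cutoff: Optional[MetricsSet]
    n_negative: int
    n_records: int
    feasible: bool


def _arrays(records: Sequence[AnnotatedRecord]):
    dd = np.array([r.ddimer for r in records], dtype=float)
    pe = np.array([r.pe for r in records], dtype=bool)
    return dd, pe


def derive_cutoff(
    records: Sequence[AnnotatedRecord],
    target_npv: float,
    stratum_label: str = "",
    ci_method: str = "wilson",
) -> CutoffResult:
    """Largest observed D-dimer value usable as a cutoff with NPV ≥ target.

    ``records`` must already be restricted to the intended stratum (and,
    for the rule-out use case, to Wells score < 6.5).  When no candidate
    with at least one negative meets the target, the result carries
    ``feasible=False`` and the smallest candidate.
    """
    if not records:
        raise ValueError("empty stratum")
    if not 0.0 < target_npv <= 1.0:
        raise ValueError(f"target_npv must be in (0, 1], got {target_npv}")

    dd, pe = _arrays(records)
    order = np.argsort(dd, kind="stable")
    dd_sorted = dd[order]
    nonpe_sorted = (~pe)[order]
    candidates = np.unique(dd_sorted)
    # negatives below candidate c: records strictly less than c
    n_below = np.searchsorted(dd_sorted, candidates, side="left")
    nonpe_cum = np.concatenate([[0], np.cumsum(nonpe_sorted)])
    nonpe_below = nonpe_cum[n_below]

    with np.errstate(invalid="ignore", divide="ignore"):
        npv = np.where(n_below > 0, nonpe_below / np.maximum(n_below, 1), np.nan)
    feasible_mask = (n_below > 0) & (npv >= target_npv)
    if feasible_mask.any():
        cutoff = float(candidates[np.flatnonzero(feasible_mask)[-1]])
        feasible = True
    else:
        cutoff = float(candidates[0])
        feasible = False

    table = confusion_at_cutoff(records, cutoff)
    return CutoffResult(
        stratum_label=stratum_label,
        target_npv=target_npv,
        cutoff=cutoff,
        metrics_at_cutoff=metrics(table, ci_method=ci_method),
        n_negative=table.tn + table.fn,
        n_records=len(records),
        feasible=feasible,
    )


def evaluate_fixed_cutoffs(
    records: Sequence[AnnotatedRecord],
    cutoffs: Sequence[float],
    target_npv: float = 0.99,
    stratum_label: str = "",
    ci_method: str = "wilson",
) -> list[CutoffResult]:
    """Metrics at externally fixed cutoffs (no search); the feasibility flag
    records whether each cutoff's NPV meets ``target_npv``."""
    if not records:
        raise ValueError("empty record list")
    results = []
    for cutoff in cutoffs:
        if not cutoff > 0:
            raise ValueError(f"cutoff must be > 0, got {cutoff}")
        table = confusion_at_cutoff(records, cutoff)
        mset = metrics(table, ci_method=ci_method)
        feasible = mset.npv.defined and mset.npv.value >= target_npv
        results.append(
            CutoffResult(
                stratum_label=stratum_label,
                target_npv=target_npv,
                cutoff=float(cutoff),
                metrics_at_cutoff=mset,
                n_negative=table.tn + table.fn,
                n_records=len(records),
                feasible=feasible,
            )
        )
    return results


def crp_adjusted_cutoffs(
    records: Sequence[AnnotatedRecord],
    crp_thresholds: Sequence[float],
    target_npvs: Sequence[float] = (0.99, 0.95),
    ci_method: str = "wilson",
) -> list[CutoffResult]:
    """Derive cutoffs on CRP-restricted subsets (crp ≥ threshold), one
    result per (threshold, target) pair.

    An empty subset yields a flagged placeholder row (``cutoff=None``,
    ``feasible=False``) rather than an error.
    """
    if list(crp_thresholds) != sorted(crp_thresholds):
        raise ValueError("crp_thresholds must be sorted ascending")
    results = []
    for threshold in crp_thresholds:
        subset = [r for r in records if r.crp >= threshold]
        for target in target_npvs:
            label = f"crp_gte_{threshold:g}"
            if not subset:
                results.append(
                    CutoffResult(
                        stratum_label=label,
                        target_npv=target,
                        cutoff=None,
                        metrics_at_cutoff=None,
                        n_negative=0,
                        n_records=0,
                        feasible=False,
                    )
                )
            else:
                results.append(
                    derive_cutoff(
                        subset, target, stratum_label=label, ci_method=ci_method
                    )
                )
    return results
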