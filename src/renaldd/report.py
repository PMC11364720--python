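"""End-to-end pipeline: exclusions, annotation, and the six report tables
(stratified descriptives, performance at the standard cutoff, Wells classes,
per-item odds ratios, the D-dimer regression, derived cutoffs) plus NRI and
cost comparisons.

All analysis constants (standard cutoff, NPV targets, comparator cutoffs,
unit cost, CRP thresholds, Wells high-risk bound) live in
:class:`AnalysisConfig`; nothing is hard-coded in the table builders.
Numbers are kept unrounded internally; rounding happens at render time.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import cutoffs as cutoffs_mod
from .compare import (
    AgeAdjusted,
    CostResult,
    NRIResult,
    ReferAll,
    RenalAdjusted,
    Strategy,
    cost_saved,
    fit_lnddimer_regression,
    nri,
    univariate_r,
)
from .cutoffs import CutoffResult, crp_adjusted_cutoffs, derive_cutoff, evaluate_fixed_cutoffs
from .metrics import Estimate, confusion_at_cutoff, empirical_auc, metrics, odds_ratio_2x2
from .records import PatientRecord, RenalStratum, WellsClass, WELLS_ITEM_NAMES
from .scores import AnnotatedRecord, annotate_all

log = logging.getLogger("renaldd")

_STRATA = (RenalStratum.GTE60, RenalStratum.S30_59, RenalStratum.LT30)
_CLASSES = (WellsClass.LOW, WellsClass.MODERATE, WellsClass.HIGH)


@dataclass(frozen=True)
class AnalysisConfig:
    standard_cutoff: float = 500.0
    target_npv_primary: float = 0.99
    target_npv_secondary: float = 0.95
    fixed_comparator_cutoffs: dict = field(
        default_factory=lambda: {"s30_59": 1306.0, "lt30": 1663.0}
    )
    crp_thresholds: tuple = (50.0, 100.0, 150.0)
    unit_cost_chf: float = 488.0
    wells_high_threshold: float = 6.5
    ci_method: str = "wilson"
    include_high_wells: bool = False  # include Wells >= 6.5 in cutoff search
    crp_floor: float = 1.0

    def validate(self) -> None:
        if not self.standard_cutoff > 0:
            raise ValueError("standard_cutoff must be > 0")
        for name in ("target_npv_primary", "target_npv_secondary"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.unit_cost_chf < 0:
            raise ValueError("unit_cost_chf must be >= 0")
        if self.ci_method not in ("wilson", "clopper_pearson"):
            raise ValueError(f"unknown ci_method {self.ci_method!r}")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=2, sort_keys=True)
            handle.write("\n")

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        data = dict(data)
        if "crp_thresholds" in data:
            data["crp_thresholds"] = tuple(data["crp_thresholds"])
        config = cls(**data)
        config.validate()
        return config

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as handle:
            return cls.from_dict(json.load(handle))


def apply_exclusions(
    records: Sequence[PatientRecord],
) -> tuple[list[PatientRecord], list[dict]]:
    """Apply the study exclusions (age < 18, then therapeutic
    anticoagulation) and log each with a reason."""
    kept: list[PatientRecord] = []
    excluded: list[dict] = []
    for rec in records:
        if rec.age < 18:  # unreachable for validated records; kept for raw input
            reason = "age_under_18"
        elif rec.anticoagulated:
            reason = "anticoagulated"
        else:
            kept.append(rec)
            continue
        excluded.append({"id": rec.id, "reason": reason})
        log.info("excluded record %s: %s", rec.id, reason)
    return kept, excluded


def _median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.median(values)),
        float(np.percentile(values, 25)),
        float(np.percentile(values, 75)),
    )


def descriptives_by_stratum(
    records: Sequence[AnnotatedRecord], config: AnalysisConfig
) -> dict:
    """Per-renal-stratum counts, D-dimer median/IQR, sub-cutoff counts and
    PE counts."""
    out = {}
    for stratum in _STRATA:
        sub = [r for r in records if r.renal_stratum is stratum]
        if not sub:
            out[stratum.value] = {"n": 0}
            continue
        dd = np.array([r.ddimer for r in sub])
        med, q1, q3 = _median_iqr(dd)
        n_below = int((dd < config.standard_cutoff).sum())
        n_pe = sum(r.pe for r in sub)
        out[stratum.value] = {
            "n": len(sub),
            "ddimer_median": med,
            "ddimer_q1": q1,
            "ddimer_q3": q3,
            "n_below_standard": n_below,
            "pct_below_standard": n_below / len(sub),
            "n_pe": n_pe,
            "pe_prevalence": n_pe / len(sub),
        }
    return out


def performance_at_standard(
    records: Sequence[AnnotatedRecord], config: AnalysisConfig
) -> dict:
    """Metrics at the standard cutoff for all patients and per stratum."""
    out = {}
    groups = {"all": list(records)}
    for stratum in _STRATA:
        groups[stratum.value] = [r for r in records if r.renal_stratum is stratum]
    for label, sub in groups.items():
        if not sub:
            out[label] = None
            continue
        table = confusion_at_cutoff(sub, config.standard_cutoff)
        out[label] = {
            "table": table,
            "metrics": metrics(table, ci_method=config.ci_method),
        }
    return out


def wells_class_table(records: Sequence[AnnotatedRecord]) -> dict:
    n_total = len(records)
    out = {}
    for cls in _CLASSES:
        sub = [r for r in records if r.wells_class is cls]
        n_pe = sum(r.pe for r in sub)
        out[cls.value] = {
            "n": len(sub),
            "pct": len(sub) / n_total if n_total else None,
            "n_pe": n_pe,
            "pe_prevalence": n_pe / len(sub) if sub else None,
        }
    return out


def wells_item_odds_ratios(records: Sequence[AnnotatedRecord]) -> dict:
    """Per-Wells-item 2×2 odds ratio of the item against PE."""
    out = {}
    for name in WELLS_ITEM_NAMES:
        a = sum(1 for r in records if getattr(r.wells_items, name) and r.pe)
        b = sum(1 for r in records if getattr(r.wells_items, name) and not r.pe)
        c = sum(1 for r in records if not getattr(r.wells_items, name) and r.pe)
        d = sum(1 for r in records if not getattr(r.wells_items, name) and not r.pe)
        out[name] = odds_ratio_2x2(a, b, c, d)
    return out


def derived_cutoff_table(
    records: Sequence[AnnotatedRecord], config: AnalysisConfig
) -> dict:
    """NPV-constrained cutoffs per eGFR stratum and CRP threshold, plus the
    externally fixed comparator cutoffs, on the Wells < 6.5 population
    (unless ``include_high_wells``)."""
    pool = (
        list(records)
        if config.include_high_wells
        else [r for r in records if r.wells_score < config.wells_high_threshold]
    )
    targets = (config.target_npv_primary, config.target_npv_secondary)
    rows: list[CutoffResult] = []
    for stratum in (RenalStratum.S30_59, RenalStratum.LT30):
        sub = [r for r in pool if r.renal_stratum is stratum]
        if not sub:
            continue
        for target in targets:
            rows.append(
                derive_cutoff(
                    sub, target, stratum_label=stratum.value, ci_method=config.ci_method
                )
            )
        fixed = config.fixed_comparator_cutoffs.get(stratum.value)
        if fixed is not None:
            rows.extend(
                evaluate_fixed_cutoffs(
                    sub,
                    [fixed],
                    target_npv=config.target_npv_primary,
                    stratum_label=f"{stratum.value}_fixed",
                    ci_method=config.ci_method,
                )
            )
    rows.extend(
        crp_adjusted_cutoffs(
            pool,
            config.crp_thresholds,
            target_npvs=targets,
            ci_method=config.ci_method,
        )
    )
    return {"rows": rows, "n_pool": len(pool)}


def comparison_tables(
    records: Sequence[AnnotatedRecord],
    config: AnalysisConfig,
    derived: dict,
) -> dict:
    """NRI set (on eGFR < 60 patients) and avoided-CTA cost per impaired
    stratum, using the cutoffs just derived at the primary NPV target."""
    derived_by_stratum = {
        row.stratum_label: row.cutoff
        for row in derived["rows"]
        if row.target_npv == config.target_npv_primary and row.feasible
    }
    renal = RenalAdjusted(
        gte60=config.standard_cutoff,
        s30_59=derived_by_stratum.get(
            RenalStratum.S30_59.value, config.standard_cutoff
        ),
        lt30=derived_by_stratum.get(RenalStratum.LT30.value, config.standard_cutoff),
    )
    standard = AgeAdjusted()
    refer_all = ReferAll()

    impaired = [
        r for r in records if r.renal_stratum is not RenalStratum.GTE60
    ]
    nri_set = {
        "standard_vs_referall": nri(impaired, refer_all, standard),
        "renal_vs_referall": nri(impaired, refer_all, renal),
        "renal_vs_standard": nri(impaired, standard, renal),
    }

    pool = [r for r in records if r.wells_score < config.wells_high_threshold]
    costs = {}
    for stratum in (RenalStratum.S30_59, RenalStratum.LT30):
        sub = [r for r in pool if r.renal_stratum is stratum]
        costs[stratum.value] = cost_saved(
            sub,
            standard,
            renal,
            config.unit_cost_chf,
            stratum_label=stratum.value,
        )
    return {"nri": nri_set, "cost": costs, "renal_strategy": renal.to_spec()}


def run_pipeline(
    records: Sequence[PatientRecord], config: Optional[AnalysisConfig] = None
) -> dict:
    """Full analysis on raw patient records: exclusions, annotation, all six
    report tables, AUC, correlations, NRI and cost results.

    Deterministic: identical inputs yield an identical bundle.
    """
    config = config or AnalysisConfig()
    config.validate()
    kept, excluded = apply_exclusions(records)
    if not kept:
        raise ValueError("empty cohort after exclusions")
    annotated = annotate_all(kept)

    derived = derived_cutoff_table(annotated, config)
    both_classes = 0 < sum(r.pe for r in annotated) < len(annotated)
    bundle = {
        "n_input": len(records),
        "n_included": len(kept),
        "excluded": excluded,
        "table1_descriptives": descriptives_by_stratum(annotated, config),
        "table2_performance": performance_at_standard(annotated, config),
        "table3_wells_classes": wells_class_table(annotated),
        "table4_item_odds_ratios": wells_item_odds_ratios(annotated),
        "table5_regression": fit_lnddimer_regression(
            annotated, crp_floor=config.crp_floor
        ),
        "table6_derived_cutoffs": derived,
        "auc": empirical_auc(annotated) if both_classes else None,
        "correlations": _correlations(annotated),
        "comparison": comparison_tables(annotated, config, derived),
        "config": dataclasses.asdict(config),
    }
    return bundle


def _correlations(records: Sequence[AnnotatedRecord]) -> dict:
    out = {}
    for x_field in ("creatinine", "egfr", "crp"):
        try:
            r, p = univariate_r(records, x_field, "ddimer")
        except ValueError:
            out[x_field] = None
        else:
            out[x_field] = {"r": r, "p": p}
    return out


# ---------------------------------------------------------------------------
# Serialization of the bundle
# ---------------------------------------------------------------------------

def _jsonify(obj):
    import pandas as pd

    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Estimate):
        return {"value": obj.value, "ci": list(obj.ci) if obj.ci else None}
    if isinstance(obj, pd.DataFrame):
        return {
            idx: {col: _jsonify(v) for col, v in row.items()}
            for idx, row in obj.iterrows()
        }
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _jsonify(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if hasattr(obj, "value"):  # enums
        return obj.value
    return str(obj)


def bundle_to_json(bundle: dict, path) -> None:
    """Write the report bundle as deterministic (sorted-key) JSON."""
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(_jsonify(bundle), handle, indent=2, sort_keys=True)
        handle.write("\n")


def render_tables(bundle: dict) -> str:
    """Human-readable TSV rendering of the six tables (rounded here only)."""
    lines: list[str] = []

    def r3(x):
        if x is None:
            return "NA"
        if isinstance(x, Estimate):
            return "undefined" if not x.defined else f"{x.value:.3f}"
        return f"{x:.3f}" if isinstance(x, float) else str(x)

    lines.append("# Table 1: descriptives by renal stratum")
    lines.append("stratum\tn\tddimer_median\tddimer_iqr\tn_below_standard\tn_pe")
    for label, row in bundle["table1_descriptives"].items():
        if row.get("n", 0) == 0:
            lines.append(f"{label}\t0\tNA\tNA\tNA\tNA")
            continue
        lines.append(
            f"{label}\t{row['n']}\t{row['ddimer_median']:.0f}"
            f"\t{row['ddimer_q1']:.0f}-{row['ddimer_q3']:.0f}"
            f"\t{row['n_below_standard']}\t{row['n_pe']}"
        )

    lines.append("")
    lines.append("# Table 2: performance at the standard cutoff")
    lines.append("group\tsensitivity\tspecificity\tppv\tnpv\tplr\tnlr\taccuracy")
    for label, row in bundle["table2_performance"].items():
        if row is None:
            continue
        m = row["metrics"]
        lines.append(
            f"{label}\t{r3(m.sensitivity)}\t{r3(m.specificity)}\t{r3(m.ppv)}"
            f"\t{r3(m.npv)}\t{r3(m.plr)}\t{r3(m.nlr)}\t{r3(m.accuracy)}"
        )

    lines.append("")
    lines.append("# Table 3: Wells risk classes")
    lines.append("class\tn\tpct\tn_pe\tprevalence")
    for label, row in bundle["table3_wells_classes"].items():
        lines.append(
            f"{label}\t{row['n']}\t{r3(row['pct'])}\t{row['n_pe']}"
            f"\t{r3(row['pe_prevalence'])}"
        )

    lines.append("")
    lines.append("# Table 4: Wells item odds ratios")
    lines.append("item\todds_ratio\tci_low\tci_high\tp_value")
    for name, orr in bundle["table4_item_odds_ratios"].items():
        lines.append(
            f"{name}\t{orr.value:.2f}\t{orr.ci[0]:.2f}\t{orr.ci[1]:.2f}"
            f"\t{orr.p_value:.4g}"
        )

    lines.append("")
    lines.append("# Table 5: ln(D-dimer) regression")
    lines.append("covariate\testimate\tse\tp_value")
    for name, row in bundle["table5_regression"].iterrows():
        lines.append(
            f"{name}\t{row['estimate']:.4f}\t{row['se']:.4f}\t{row['p_value']:.4g}"
        )

    lines.append("")
    lines.append("# Table 6: derived and fixed cutoffs")
    lines.append(
        "stratum\ttarget_npv\tcutoff\tfeasible\tn_negative\tsensitivity"
        "\tspecificity\tppv\tnpv"
    )
    for row in bundle["table6_derived_cutoffs"]["rows"]:
        if row.cutoff is None:
            lines.append(
                f"{row.stratum_label}\t{row.target_npv}\tNA\tFalse\t0\tNA\tNA\tNA\tNA"
            )
            continue
        m = row.metrics_at_cutoff
        lines.append(
            f"{row.stratum_label}\t{row.target_npv}\t{row.cutoff:.0f}"
            f"\t{row.feasible}\t{row.n_negative}\t{r3(m.sensitivity)}"
            f"\t{r3(m.specificity)}\t{r3(m.ppv)}\t{r3(m.npv)}"
        )

    return "\n".join(lines) + "\n"
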