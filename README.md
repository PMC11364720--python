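# renaldd

Renal-function-adapted D-dimer cutoff analysis for ruling out pulmonary
embolism (PE) in emergency-department cohorts.

The package implements, as a reusable and tested pipeline:

- **Clinical calculators** (`renaldd.scores`): CKD-EPI eGFR from serum
  creatinine, renal-function strata (≥60 / 30–59 / <30 ml/min), the
  two-level Wells score and risk classes, the YEARS rule-out check, and the
  conventional age-adjusted D-dimer cutoff.
- **Diagnostic metrics** (`renaldd.metrics`): 2×2 confusion tables for a
  D-dimer cutoff against CTA-confirmed PE, sensitivity/specificity/PPV/NPV/
  likelihood ratios/accuracy with 95% CIs (Wilson by default,
  Clopper–Pearson switch), empirical Mann–Whitney AUC with Hanley–McNeil CI,
  and 2×2 odds ratios with Haldane–Anscombe correction.
- **NPV-constrained cutoff derivation** (`renaldd.cutoffs`): per-stratum
  search over observed D-dimer values for the largest cutoff whose negative
  predictive value meets a safety target (0.99 / 0.95), for eGFR and CRP
  strata, plus evaluation of externally fixed comparator cutoffs.
- **Strategy comparison** (`renaldd.compare`): two-category net
  reclassification improvement, avoided-CTA cost accounting, OLS regression
  of ln(D-dimer) on clinical determinants, univariate correlations.
- **Synthetic cohorts** (`renaldd.cohort`): a seeded generator whose
  log-linear D-dimer backbone uses published regression coefficients as
  ground truth, with configurable demographic/renal/Wells marginals.
- **Pipeline + CLI** (`renaldd.report`, `renaldd.cli`): exclusions,
  annotation, and report tables (descriptives, performance at 500 µg/l,
  Wells classes, per-item odds ratios, regression, derived cutoffs, NRI,
  cost results) as a deterministic JSON bundle and TSV tables.

## CLI

```sh
# generate a synthetic cohort CSV (fully reproducible by seed)
renaldd simulate --seed 7 --n 1369 --out cohort.csv

# run the full analysis -> JSON bundle (+ optional TSV tables)
renaldd analyze cohort.csv --out report.json --tables tables.tsv

# derive the NPV-constrained cutoff for one renal stratum
renaldd derive-cutoffs cohort.csv --stratum s30_59 --target-npv 0.99

# NRI + avoided-CTA cost between two strategies
renaldd compare cohort.csv \
    --old '{"type": "age_adjusted"}' \
    --new '{"type": "renal_adjusted", "cutoffs": {"gte60": 500, "s30_59": 1480, "lt30": 1351}}'
```

Shared flags: `--seed`, `--config`, `--out`, `--ci-method {wilson,clopper_pearson}`,
`--include-high-wells`.

### Strategy spec format (JSON)

```json
{"type": "fixed", "cutoff": 500}
{"type": "age_adjusted"}
{"type": "renal_adjusted", "cutoffs": {"gte60": 500, "s30_59": 1480, "lt30": 1351}}
{"type": "refer_all"}
```

### Cohort CSV schema

UTF-8 CSV, header row, one record per row, booleans as 0/1, empty
`pe_location` when absent. Columns: `id, age, sex, black, creatinine, crp,
ddimer, clinical_dvt_signs, pe_most_likely, tachycardia_gt100,
surgery_or_immobilization, previous_pe_dvt, hemoptysis, malignancy,
pregnancy_perinatal, anticoagulated, pe, pe_location`. Units: creatinine
µmol/l, CRP mg/l, D-dimer µg/l. The reader validates every row (age ≥ 18,
positive creatinine/D-dimer, pregnancy only in females, location only with
PE) and reports row-numbered errors.

### Generator config (JSON)

`GeneratorConfig.to_json` / `from_json` round-trip the full generative
parameterization: cohort size, seed, the coefficient vector and residual sd
of the ln(D-dimer) model, age/sex marginals, renal-stratum probabilities and
per-stratum creatinine distributions, CRP distribution, the seven Wells item
marginals, PE prevalence per Wells class, pregnancy probability, and PE
location probabilities. See `renaldd.cohort.GeneratorConfig` for defaults.

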