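"""Synthetic ED cohort generator.

The generative backbone is a log-linear model for D-dimer:

    ln(ddimer) = β·x + N(0, σ²),
    x = (1, age, female, pe, malignancy, pregnancy, ln eGFR, ln max(CRP, floor))

with the β defaults fixed to the published multivariate point estimates.
Demographics, renal strata, Wells items and PE prevalence by Wells class are
drawn from configurable marginals whose defaults target the study cohort's
printed summary statistics.  All randomness flows through a single
``numpy.random.Generator`` seeded from the config, so cohorts are exactly
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .records import (
    PatientRecord,
    PELocation,
    RenalStratum,
    Sex,
    WellsClass,
    WellsItems,
    WELLS_ITEM_NAMES,
)
from .scores import ckd_epi_egfr, wells_class, WELLS_WEIGHTS

#: Maximum rejection-sampling attempts for creatinine within a renal stratum.
MAX_REJECTION_ROUNDS = 1000

_STRATA_ORDER = (RenalStratum.GTE60, RenalStratum.S30_59, RenalStratum.LT30)
_CLASS_ORDER = (WellsClass.LOW, WellsClass.MODERATE, WellsClass.HIGH)
_LOCATION_ORDER = (
    PELocation.PERIPHERAL_SUBSEGMENTAL,
    PELocation.SEGMENTAL,
    PELocation.PARACENTRAL,
    PELocation.CENTRAL,
)


@dataclass(frozen=True)
class BetaVector:
    """Coefficients of the log-linear D-dimer model.

    Defaults are the published multivariate OLS point estimates; the
    intercept is not printed and was calibrated once (together with the
    residual sd in :class:`GeneratorConfig`) so the synthetic median
    D-dimer in the eGFR ≥ 60 stratum lands near 1096 µg/l while the
    rule-out cutoff derived in the impaired strata stays above the
    standard 500 µg/l.
    """

    intercept: float = 7.57
    age: float = 0.012
    female: float = -0.07
    pe: float = 0.959
    malignancy: float = 0.237
    pregnancy: float = 0.918
    ln_egfr: float = -0.3467
    ln_crp: float = 0.0297

    NAMES = (
        "intercept",
        "age",
        "female",
        "pe",
        "malignancy",
        "pregnancy",
        "ln_egfr",
        "ln_crp",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.NAMES], dtype=float)


@dataclass(frozen=True)
class LognormalParams:
    """Parameters of a lognormal draw: median on the natural scale and the
    standard deviation of the log."""

    median: float
    log_sd: float

    def __post_init__(self) -> None:
        if not self.median > 0:
            raise ValueError("lognormal median must be > 0")
        if self.log_sd < 0:
            raise ValueError("lognormal log_sd must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic cohort, including the seed."""

    n: int = 1369
    seed: int = 0
    beta: BetaVector = field(default_factory=BetaVector)
    sigma: float = 0.45
    crp_floor: float = 1.0
    age_median: float = 66.0
    age_sd: float = 18.5
    age_max: int = 100
    female_frac: float = 0.53
    egfr_strata_probs: dict = field(
        default_factory=lambda: {"gte60": 0.79, "s30_59": 0.19, "lt30": 0.02}
    )
    creatinine_dist: dict = field(
        default_factory=lambda: {
            "gte60": LognormalParams(median=76.0, log_sd=0.18),
            "s30_59": LognormalParams(median=125.0, log_sd=0.18),
            "lt30": LognormalParams(median=280.0, log_sd=0.25),
        }
    )
    crp_dist: LognormalParams = field(
        default_factory=lambda: LognormalParams(median=10.0, log_sd=1.5)
    )
    wells_item_probs: dict = field(
        default_factory=lambda: {
            "clinical_dvt_signs": 0.14,
            "pe_most_likely": 0.15,
            "tachycardia_gt100": 0.24,
            "surgery_or_immobilization": 0.22,
            "previous_pe_dvt": 0.20,
            "hemoptysis": 0.02,
            "malignancy": 0.10,
        }
    )
    pe_prev_by_class: dict = field(
        default_factory=lambda: {"low": 0.02, "moderate": 0.36, "high": 0.54}
    )
    pregnancy_prob: float = 0.01
    pe_location_probs: tuple = (42 / 229, 76 / 229, 37 / 229, 74 / 229)

    @property
    def malignancy_prob(self) -> float:
        """Marginal probability of active malignancy (the Wells item doubles
        as the regression covariate)."""
        return self.wells_item_probs["malignancy"]

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not self.crp_floor > 0:
            raise ValueError("crp_floor must be > 0")
        probs = [
            ("female_frac", self.female_frac),
            ("pregnancy_prob", self.pregnancy_prob),
            *((f"wells_item_probs[{k}]", v) for k, v in self.wells_item_probs.items()),
            *((f"pe_prev_by_class[{k}]", v) for k, v in self.pe_prev_by_class.items()),
            *((f"egfr_strata_probs[{k}]", v) for k, v in self.egfr_strata_probs.items()),
            *((f"pe_location_probs[{i}]", v) for i, v in enumerate(self.pe_location_probs)),
        ]
        for name, value in probs:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if set(self.wells_item_probs) != set(WELLS_ITEM_NAMES):
            raise ValueError("wells_item_probs must cover exactly the 7 Wells items")
        if set(self.egfr_strata_probs) != {s.value for s in _STRATA_ORDER}:
            raise ValueError("egfr_strata_probs must cover gte60/s30_59/lt30")
        if set(self.pe_prev_by_class) != {c.value for c in _CLASS_ORDER}:
            raise ValueError("pe_prev_by_class must cover low/moderate/high")
        if set(self.creatinine_dist) != {s.value for s in _STRATA_ORDER}:
            raise ValueError("creatinine_dist must cover gte60/s30_59/lt30")
        if abs(sum(self.egfr_strata_probs.values()) - 1.0) > 1e-9:
            raise ValueError("egfr_strata_probs must sum to 1")
        if abs(sum(self.pe_location_probs) - 1.0) > 1e-9:
            raise ValueError("pe_location_probs must sum to 1")
        if not self.age_sd > 0:
            raise ValueError("age_sd must be > 0")
        if self.age_max < 18:
            raise ValueError("age_max must be >= 18")

    # -- JSON round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["creatinine_dist"] = {
            k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
            for k, v in self.creatinine_dist.items()
        }
        d["pe_location_probs"] = list(self.pe_location_probs)
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.to_dict(), handle, indent=2, sort_keys=True)
            handle.write("\n")

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        data = dict(data)
        if "beta" in data and isinstance(data["beta"], dict):
            data["beta"] = BetaVector(**data["beta"])
        if "crp_dist" in data and isinstance(data["crp_dist"], dict):
            data["crp_dist"] = LognormalParams(**data["crp_dist"])
        if "creatinine_dist" in data:
            data["creatinine_dist"] = {
                k: LognormalParams(**v) if isinstance(v, dict) else v
                for k, v in data["creatinine_dist"].items()
            }
        if "pe_location_probs" in data:
            data["pe_location_probs"] = tuple(data["pe_location_probs"])
        config = cls(**data)
        config.validate()
        return config

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as handle:
            return cls.from_dict(json.load(handle))


class GenerationError(RuntimeError):
    """Raised when rejection sampling cannot place creatinine in its stratum."""


def _draw_creatinine(
    rng: np.random.Generator,
    stratum: RenalStratum,
    params: LognormalParams,
    age: np.ndarray,
    female: np.ndarray,
    black: np.ndarray,
) -> np.ndarray:
    """Draw creatinine for every record of one stratum, rejection-sampling
    until the implied CKD-EPI eGFR falls inside the stratum."""
    n = age.shape[0]
    creat = np.empty(n, dtype=float)
    pending = np.ones(n, dtype=bool)
    low, high = {
        RenalStratum.GTE60: (60.0, math.inf),
        RenalStratum.S30_59: (30.0, 60.0),
        RenalStratum.LT30: (0.0, 30.0),
    }[stratum]
    mu = math.log(params.median)
    for _ in range(MAX_REJECTION_ROUNDS):
        if not pending.any():
            return creat
        idx = np.flatnonzero(pending)
        draw = rng.lognormal(mean=mu, sigma=params.log_sd, size=idx.size)
        egfr = ckd_epi_egfr(draw, age[idx], female[idx], black[idx])
        ok = (egfr >= low) & (egfr < high)
        creat[idx[ok]] = draw[ok]
        pending[idx[ok]] = False
    raise GenerationError(
        f"creatinine rejection sampling exhausted {MAX_REJECTION_ROUNDS} rounds "
        f"for stratum {stratum.value}; creatinine_dist is misconfigured"
    )


def generate_arrays(config: GeneratorConfig) -> dict:
    """Generate the cohort as a dict of numpy arrays (column-oriented).

    The fixed draw order (age, sex, stratum, creatinine per stratum, CRP,
    pregnancy, Wells items, PE, PE location, noise) is part of the
    reproducibility contract.
    """
    config.validate()
    n = config.n
    rng = np.random.default_rng(config.seed)

    age = np.clip(
        np.rint(rng.normal(config.age_median, config.age_sd, size=n)),
        18,
        config.age_max,
    ).astype(int)
    female = rng.random(n) < config.female_frac
    black = np.zeros(n, dtype=bool)

    strata_probs = [config.egfr_strata_probs[s.value] for s in _STRATA_ORDER]
    stratum_idx = rng.choice(len(_STRATA_ORDER), size=n, p=strata_probs)

    creatinine = np.empty(n, dtype=float)
    for k, stratum in enumerate(_STRATA_ORDER):
        mask = stratum_idx == k
        if mask.any():
            creatinine[mask] = _draw_creatinine(
                rng,
                stratum,
                config.creatinine_dist[stratum.value],
                age[mask],
                female[mask],
                black[mask],
            )

    crp = rng.lognormal(
        mean=math.log(config.crp_dist.median), sigma=config.crp_dist.log_sd, size=n
    )
    pregnancy = female & (rng.random(n) < config.pregnancy_prob)

    items = {
        name: rng.random(n) < config.wells_item_probs[name]
        for name in WELLS_ITEM_NAMES
    }
    score = np.zeros(n, dtype=float)
    for name, weight in WELLS_WEIGHTS.items():
        score += weight * items[name]
    prev = np.empty(n, dtype=float)
    prev[score < 2.0] = config.pe_prev_by_class["low"]
    prev[(score >= 2.0) & (score <= 6.0)] = config.pe_prev_by_class["moderate"]
    prev[score > 6.0] = config.pe_prev_by_class["high"]
    pe = rng.random(n) < prev

    location = np.full(n, -1, dtype=int)
    n_pe = int(pe.sum())
    if n_pe:
        location[pe] = rng.choice(
            len(_LOCATION_ORDER), size=n_pe, p=list(config.pe_location_probs)
        )

    egfr = ckd_epi_egfr(creatinine, age, female, black)
    design = np.column_stack(
        [
            np.ones(n),
            age.astype(float),
            female.astype(float),
            pe.astype(float),
            items["malignancy"].astype(float),
            pregnancy.astype(float),
            np.log(egfr),
            np.log(np.maximum(crp, config.crp_floor)),
        ]
    )
    ln_dd = design @ config.beta.as_array()
    if config.sigma > 0:
        ln_dd = ln_dd + rng.normal(0.0, config.sigma, size=n)
    ddimer = np.exp(ln_dd)

    return {
        "age": age,
        "female": female,
        "black": black,
        "stratum_idx": stratum_idx,
        "creatinine": creatinine,
        "crp": crp,
        "pregnancy": pregnancy,
        "items": items,
        "pe": pe,
        "location_idx": location,
        "ddimer": ddimer,
        "egfr": egfr,
        "wells_score": score,
    }


def generate_cohort(config: GeneratorConfig) -> list[PatientRecord]:
    """Generate ``config.n`` validated patient records, reproducibly."""
    cols = generate_arrays(config)
    n = config.n
    width = len(str(n))
    records = []
    for i in range(n):
        loc = cols["location_idx"][i]
        records.append(
            PatientRecord(
                id=f"syn-{i:0{width}d}",
                age=int(cols["age"][i]),
                sex=Sex.FEMALE if cols["female"][i] else Sex.MALE,
                black=bool(cols["black"][i]),
                creatinine=float(cols["creatinine"][i]),
                crp=float(cols["crp"][i]),
                ddimer=float(cols["ddimer"][i]),
                wells_items=WellsItems(
                    **{k: bool(v[i]) for k, v in cols["items"].items()}
                ),
                pregnancy_perinatal=bool(cols["pregnancy"][i]),
                anticoagulated=False,
                pe=bool(cols["pe"][i]),
                pe_location=_LOCATION_ORDER[loc] if loc >= 0 else None,
            )
        )
    return records
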