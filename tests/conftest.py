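import dataclasses

import numpy as np
import pytest

from renaldd import (
    AnnotatedRecord,
    GeneratorConfig,
    PatientRecord,
    Sex,
    WellsItems,
    annotate_all,
    generate_cohort,
)
from renaldd.records import RenalStratum, WellsClass


def make_record(
    ddimer: float,
    pe: bool = False,
    *,
    rid: str = "r",
    age: int = 70,
    sex: Sex = Sex.MALE,
    creatinine: float = 130.0,
    crp: float = 5.0,
    items: WellsItems = WellsItems(),
    pregnancy: bool = False,
    anticoagulated: bool = False,
) -> PatientRecord:
    """Hand-built record; the default creatinine/age put eGFR in 30-59."""
    return PatientRecord(
        id=rid,
        age=age,
        sex=sex,
        creatinine=creatinine,
        crp=crp,
        ddimer=ddimer,
        wells_items=items,
        pregnancy_perinatal=pregnancy,
        anticoagulated=anticoagulated,
        pe=pe,
    )


def make_annotated(ddimers, pe_flags, **kwargs) -> list[AnnotatedRecord]:
    records = [
        make_record(dd, pe, rid=f"r{i}", **kwargs)
        for i, (dd, pe) in enumerate(zip(ddimers, pe_flags))
    ]
    return annotate_all(records)


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(n=1369, seed=0)


@pytest.fixture(scope="session")
def large_cohort():
    """n=10,000 default cohort, annotated (shared; used by several
    calibration-sensitive tests)."""
    config = GeneratorConfig(n=10_000, seed=1)
    return annotate_all(generate_cohort(config))


@pytest.fixture(scope="session")
def study_size_cohort(default_config):
    return annotate_all(generate_cohort(default_config))


@pytest.fixture(scope="session")
def reconstructed_s30_59():
    """The eGFR 30-59 stratum forced by the printed counts: n=266, 53 PE all
    at/above 500 µg/l, exactly 3 non-PE below 500."""
    ddimers = [100.0, 250.0, 400.0] + [600.0] * 210 + [900.0] * 53
    pe_flags = [False] * 213 + [True] * 53
    recs = make_annotated(ddimers, pe_flags)
    assert all(r.renal_stratum is RenalStratum.S30_59 for r in recs)
    return recs
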