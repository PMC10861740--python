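"""Shared fixtures: handmade micro-cohorts and seeded synthetic registries."""

from __future__ import annotations

import itertools

import pandas as pd
import pytest

from icubench.registry import validate_admission_frame
from icubench.synthetic import GeneratorConfig, generate_registry

_COUNTER = itertools.count()

_DEFAULT_ROW = {
    "unit_id": "U1",
    "year": 2015,
    "diagnosis_group": "OTHER",
    "admission_type": "EMERGENCY",
    "saps2": 30,
    "gcs": 12,
    "age": 60.0,
    "sex": "M",
    "operative": False,
    "premorbid_status": "NORMAL",
    "los_days": 2.0,
    "tiss_total": 80.0,
    "died_in_hospital": False,
    "organ_donor": False,
    "readmission": False,
    "icu_transfer_in": False,
}


def make_admissions(rows: list[dict]) -> pd.DataFrame:
    """Build a validated cohort frame from partial row dicts."""
    from icubench.registry import ADMISSION_COLUMNS

    if not rows:
        return validate_admission_frame(pd.DataFrame(columns=ADMISSION_COLUMNS))
    full = []
    for row in rows:
        r = dict(_DEFAULT_ROW)
        r.update(row)
        r.setdefault("admission_id", f"A{next(_COUNTER):05d}")
        full.append(r)
    return validate_admission_frame(pd.DataFrame(full))


@pytest.fixture
def make_cohort():
    return make_admissions


@pytest.fixture(scope="session")
def small_registry():
    """Six units, one year, ~500 admissions/unit; shared read-only."""
    cfg = GeneratorConfig(seed=11, years=(2016,), admissions_per_unit_year=500)
    admissions, profiles, truth = generate_registry(cfg)
    return cfg, admissions, profiles, truth
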