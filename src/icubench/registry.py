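"""Admission/unit data model, registry I/O, exclusion cascade, diagnosis subgroups.

The canonical in-memory container for a cohort is a :class:`pandas.DataFrame`
with one row per ICU admission and the columns of :class:`Admission`.
Pydantic models define and document the record schemas; file readers apply
the same constraints with vectorized checks so that multi-year registries
(tens of thousands of rows) validate quickly while still reporting the
offending row and field.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = [
    "DiagnosisGroup", "AdmissionType", "Sex", "PremorbidStatus", "Currency",
    "DonorPolicy", "ExclusionReason", "Admission", "UnitProfile",
    "RegistryValidationError", "ADMISSION_COLUMNS", "SUBGROUPS",
    "read_admissions", "read_unit_profiles", "write_unit_profiles",
    "admissions_to_frame", "apply_exclusions", "subgroup",
]


class DiagnosisGroup(str, enum.Enum):
    NONTRAUMATIC_ICH = "NONTRAUMATIC_ICH"
    SAH = "SAH"
    TBI_MULTITRAUMA = "TBI_MULTITRAUMA"
    TBI_ISOLATED = "TBI_ISOLATED"
    OTHER = "OTHER"


NEURO_GROUPS = (
    DiagnosisGroup.NONTRAUMATIC_ICH.value,
    DiagnosisGroup.SAH.value,
    DiagnosisGroup.TBI_MULTITRAUMA.value,
    DiagnosisGroup.TBI_ISOLATED.value,
)


class AdmissionType(str, enum.Enum):
    EMERGENCY = "EMERGENCY"
    ELECTIVE = "ELECTIVE"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class PremorbidStatus(str, enum.Enum):
    NORMAL = "NORMAL"
    LIGHT = "LIGHT"
    MODERATE = "MODERATE"
    SEVERE = "SEVERE"


class Currency(str, enum.Enum):
    EUR = "EUR"
    CHF = "CHF"


class DonorPolicy(str, enum.Enum):
    """How admissions flagged as potential organ donors enter the analysis.

    EXCLUDE_ALL     drop donors from resources and outcomes (primary analysis).
    RESOURCES_ONLY  count donors' resource use, never their survivorship/outcome.
    INCLUDE_ALL     treat donors as ordinary admissions.
    """

    EXCLUDE_ALL = "EXCLUDE_ALL"
    RESOURCES_ONLY = "RESOURCES_ONLY"
    INCLUDE_ALL = "INCLUDE_ALL"


class ExclusionReason(str, enum.Enum):
    TRANSFER = "TRANSFER"
    NON_EMERGENCY = "NON_EMERGENCY"
    UNKNOWN_DISCHARGE = "UNKNOWN_DISCHARGE"
    READMISSION = "READMISSION"
    MISSING_TISS = "MISSING_TISS"
    MISSING_SEX = "MISSING_SEX"
    MISSING_GCS = "MISSING_GCS"
    ORGAN_DONOR = "ORGAN_DONOR"


class RegistryValidationError(ValueError):
    """A registry file or record violates the admission/unit schema."""


class Admission(BaseModel):
    """One ICU stay with severity, resource, and outcome fields."""

    admission_id: str
    unit_id: str
    year: int
    diagnosis_group: DiagnosisGroup
    admission_type: AdmissionType
    saps2: int = Field(ge=0)
    gcs: Optional[int] = Field(default=None, ge=3, le=15)
    age: Optional[float] = Field(default=None, ge=0)
    sex: Optional[Sex] = None
    operative: bool = False
    premorbid_status: Optional[PremorbidStatus] = None
    los_days: float = Field(gt=0)
    tiss_total: Optional[float] = Field(default=None, ge=0)
    died_in_hospital: Optional[bool] = None
    organ_donor: bool = False
    readmission: bool = False
    icu_transfer_in: bool = False


class UnitProfile(BaseModel):
    """Structural, organizational and cost attributes of one ICU."""

    unit_id: str
    beds: int = Field(gt=0)
    fte_physicians_per_bed: float = Field(gt=0)
    independent_org: bool
    currency: Currency = Currency.EUR
    ppp_factor: float = Field(default=1.0, gt=0)
    annual_direct_costs: dict[int, float]

    @field_validator("annual_direct_costs")
    @classmethod
    def _costs_nonnegative(cls, v: dict[int, float]) -> dict[int, float]:
        for year, amount in v.items():
            if amount < 0:
                raise ValueError(f"negative annual cost for year {year}")
        return {int(y): float(a) for y, a in v.items()}


ADMISSION_COLUMNS = list(Admission.model_fields)

_BOOL_COLUMNS = ["operative", "organ_donor", "readmission", "icu_transfer_in"]
_NULLABLE_BOOL_COLUMNS = ["died_in_hospital"]
_NA_TOKENS = ["", "NA"]

SUBGROUPS = [g.value for g in DiagnosisGroup] + ["NEURO_ALL", "NON_NEURO", "ALL"]


def _parse_bool(series: pd.Series, column: str, allow_missing: bool) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "t": True, "f": False,
    }
    raw = series.astype("string").str.strip().str.lower()
    out = raw.map(mapping)
    bad = out.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise RegistryValidationError(
            f"row {row}: field '{column}' has non-boolean value {series.iloc[row]!r}"
        )
    if not allow_missing and out.isna().any():
        row = int(np.flatnonzero(out.isna().to_numpy())[0])
        raise RegistryValidationError(f"row {row}: field '{column}' is missing")
    return out.astype("boolean")


def _fail(mask: pd.Series, column: str, message: str) -> None:
    if mask.any():
        row = int(np.flatnonzero(mask.to_numpy())[0])
        raise RegistryValidationError(f"row {row}: field '{column}' {message}")


def validate_admission_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce dtypes and enforce the :class:`Admission` constraints on a frame.

    Raises :class:`RegistryValidationError` naming the first offending row
    (0-based data row) and field.  Returns a new frame with canonical dtypes;
    row order is preserved.
    """
    missing = [c for c in ADMISSION_COLUMNS if c not in df.columns]
    if missing:
        raise RegistryValidationError(f"missing required columns: {missing}")
    df = df[ADMISSION_COLUMNS].copy().reset_index(drop=True)

    for col in ("admission_id", "unit_id"):
        df[col] = df[col].astype("string")
        _fail(df[col].isna(), col, "is missing")
        df[col] = df[col].astype(str)

    for col, as_int in (("year", True), ("saps2", True)):
        vals = pd.to_numeric(df[col], errors="coerce")
        _fail(vals.isna(), col, "is missing or non-numeric")
        _fail((vals % 1 != 0), col, "must be an integer")
        df[col] = vals.astype(int)
    _fail(df["saps2"] < 0, "saps2", "must be >= 0")

    for col, enum_cls, allow_missing in (
        ("diagnosis_group", DiagnosisGroup, False),
        ("admission_type", AdmissionType, False),
        ("sex", Sex, True),
        ("premorbid_status", PremorbidStatus, True),
    ):
        vals = df[col].astype("string").str.strip()
        valid = {e.value for e in enum_cls}
        bad = vals.notna() & ~vals.isin(valid)
        _fail(bad, col, f"must be one of {sorted(valid)}")
        if not allow_missing:
            _fail(vals.isna(), col, "is missing")
        df[col] = vals.astype(object).where(vals.notna(), None)

    gcs = pd.to_numeric(df["gcs"], errors="coerce")
    raw_gcs_missing = df["gcs"].isna()
    _fail(gcs.isna() & ~raw_gcs_missing, "gcs", "is non-numeric")
    _fail(gcs.notna() & ((gcs < 3) | (gcs > 15)), "gcs", "must be in 3..15")
    df["gcs"] = gcs.astype(float)

    age = pd.to_numeric(df["age"], errors="coerce")
    _fail(age.notna() & (age < 0), "age", "must be >= 0")
    df["age"] = age.astype(float)

    los = pd.to_numeric(df["los_days"], errors="coerce")
    _fail(los.isna(), "los_days", "is missing or non-numeric")
    _fail(los <= 0, "los_days", "must be > 0")
    df["los_days"] = los.astype(float)

    tiss = pd.to_numeric(df["tiss_total"], errors="coerce")
    raw_tiss_missing = df["tiss_total"].isna()
    _fail(tiss.isna() & ~raw_tiss_missing, "tiss_total", "is non-numeric")
    _fail(tiss.notna() & (tiss < 0), "tiss_total", "must be >= 0")
    df["tiss_total"] = tiss.astype(float)

    for col in _BOOL_COLUMNS:
        df[col] = _parse_bool(df[col], col, allow_missing=False)
    for col in _NULLABLE_BOOL_COLUMNS:
        df[col] = _parse_bool(df[col], col, allow_missing=True)

    return df


def read_admissions(path: Union[str, Path], sep: Optional[str] = None) -> pd.DataFrame:
    """Read and validate an admissions registry (CSV or TSV, header row).

    Empty fields and the literal token ``NA`` are treated as missing values.
    Returns a validated DataFrame, one row per admission, in file order.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        raw = pd.read_csv(
            path, sep=sep, dtype=str,
            na_values=_NA_TOKENS, keep_default_na=False,
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise OSError(f"cannot read admissions file {path}: {exc}") from exc
    return validate_admission_frame(raw)


def admissions_to_frame(admissions: list[Admission]) -> pd.DataFrame:
    """Build a cohort frame from Admission records."""
    if not admissions:
        return pd.DataFrame(columns=ADMISSION_COLUMNS)
    rows = [a.model_dump() for a in admissions]
    df = pd.DataFrame(rows)
    for col in ("diagnosis_group", "admission_type", "sex", "premorbid_status"):
        df[col] = df[col].map(lambda v: v.value if isinstance(v, enum.Enum) else v)
    return validate_admission_frame(df)


def read_unit_profiles(path: Union[str, Path]) -> dict[str, UnitProfile]:
    """Read unit profiles from a YAML or JSON document keyed by unit_id."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise RegistryValidationError(f"unit profile document {path} must be a mapping keyed by unit_id")
    profiles: dict[str, UnitProfile] = {}
    for unit_id, fields in doc.items():
        fields = dict(fields)
        fields.setdefault("unit_id", str(unit_id))
        profiles[str(unit_id)] = UnitProfile(**fields)
    return profiles


def write_unit_profiles(profiles: dict[str, UnitProfile], path: Union[str, Path]) -> None:
    doc = {
        uid: {
            "beds": p.beds,
            "fte_physicians_per_bed": p.fte_physicians_per_bed,
            "independent_org": p.independent_org,
            "currency": p.currency.value,
            "ppp_factor": p.ppp_factor,
            "annual_direct_costs": {int(y): float(a) for y, a in p.annual_direct_costs.items()},
        }
        for uid, p in profiles.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# Exclusion cascade: first matching reason wins, in this fixed order.
_EXCLUSION_ORDER = [
    (ExclusionReason.TRANSFER, lambda df: df["icu_transfer_in"].fillna(False).astype(bool)),
    (ExclusionReason.NON_EMERGENCY, lambda df: df["admission_type"] != AdmissionType.EMERGENCY.value),
    (ExclusionReason.UNKNOWN_DISCHARGE, lambda df: df["died_in_hospital"].isna()),
    (ExclusionReason.READMISSION, lambda df: df["readmission"].fillna(False).astype(bool)),
    (ExclusionReason.MISSING_TISS, lambda df: df["tiss_total"].isna()),
    (ExclusionReason.MISSING_SEX, lambda df: df["sex"].isna()),
    (ExclusionReason.MISSING_GCS, lambda df: df["gcs"].isna()),
]


def apply_exclusions(
    admissions: pd.DataFrame,
    donor_policy: Union[DonorPolicy, str] = DonorPolicy.EXCLUDE_ALL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the study exclusion cascade.

    Removes ICU-to-ICU transfers, non-emergency admissions, admissions with
    unknown hospital discharge status, readmissions, and admissions missing
    TISS, sex or GCS — recording, per excluded admission, the first matching
    reason in that fixed order.  Potential organ donors are then removed
    (``EXCLUDE_ALL``), retained flagged so downstream stages count their
    resources but not their survivorship (``RESOURCES_ONLY``), or retained
    fully (``INCLUDE_ALL``).

    Returns ``(cohort, log)`` where ``log`` has columns
    ``admission_id, reason``.
    """
    donor_policy = DonorPolicy(donor_policy)
    df = admissions.reset_index(drop=True)
    reason = pd.Series([None] * len(df), dtype=object)
    for rs, predicate in _EXCLUSION_ORDER:
        mask = predicate(df).to_numpy(dtype=bool) & reason.isna().to_numpy()
        reason[mask] = rs.value
    if donor_policy is DonorPolicy.EXCLUDE_ALL:
        mask = df["organ_donor"].fillna(False).astype(bool).to_numpy() & reason.isna().to_numpy()
        reason[mask] = ExclusionReason.ORGAN_DONOR.value

    excluded = reason.notna().to_numpy()
    log = pd.DataFrame({
        "admission_id": df.loc[excluded, "admission_id"].to_numpy(),
        "reason": reason[excluded].to_numpy(),
    })
    cohort = df.loc[~excluded].reset_index(drop=True)
    return cohort, log


def subgroup(cohort: pd.DataFrame, group: str) -> pd.DataFrame:
    """Select a diagnostic subgroup.

    ``group`` is one of the five diagnosis values, ``NEURO_ALL`` (union of the
    four neurosurgical groups), ``NON_NEURO`` (= OTHER), or ``ALL``.
    """
    if group == "ALL":
        return cohort
    if group == "NEURO_ALL":
        mask = cohort["diagnosis_group"].isin(NEURO_GROUPS)
    elif group == "NON_NEURO":
        mask = cohort["diagnosis_group"] == DiagnosisGroup.OTHER.value
    elif group in {g.value for g in DiagnosisGroup}:
        mask = cohort["diagnosis_group"] == group
    else:
        raise ValueError(f"unknown subgroup label: {group!r}")
    return cohort.loc[mask].reset_index(drop=True)
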