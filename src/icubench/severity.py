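"""SAPS II stratification and pluggable hospital-mortality risk models.

The severity axis for both standardization directions: admissions are binned
into ten SAPS II strata (0–9, 10–19, …, 80–89, ≥90) for the resource-use
reference, and a risk model supplies per-admission death probabilities for
the SMR denominator.

The registry network's own customized risk model is proprietary, so the
default here is the original published SAPS II logistic,

    logit p = -7.7631 + 0.0737 * S + 0.9971 * ln(S + 1),

and custom models can be plugged in either as a coefficient table (logit
link) or as any callable mapping a cohort frame to probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "N_STRATA", "assign_stratum", "stratum_bounds", "RiskModel",
    "default_saps2_risk", "empirical_stratum_risk", "risk_model_from_table",
]

N_STRATA = 10


def assign_stratum(saps2) -> Union[int, np.ndarray]:
    """Map SAPS II score(s) to stratum index 0–9 (floor(S/10), capped at 9).

    Scores of 90 and above all fall in the open-ended top stratum.
    """
    arr = np.asarray(saps2)
    if np.any(arr < 0):
        raise ValueError("SAPS II score must be >= 0")
    idx = np.minimum(arr // 10, N_STRATA - 1).astype(int)
    return int(idx) if np.isscalar(saps2) or arr.ndim == 0 else idx


def stratum_bounds(index: int) -> tuple[int, Union[int, None]]:
    """Inclusive (lower, upper) score bounds of a stratum; top stratum is unbounded."""
    if not 0 <= index < N_STRATA:
        raise ValueError(f"stratum index must be in 0..{N_STRATA - 1}")
    lower = 10 * index
    upper = None if index == N_STRATA - 1 else 10 * index + 9
    return lower, upper


@dataclass(frozen=True)
class RiskModel:
    """A named mapping from admissions to hospital-death probabilities.

    ``predict`` takes a cohort DataFrame and returns an array of
    probabilities strictly inside (0, 1) — or exactly the observed stratum
    rates for the empirical calibration model, which may hit 0 or 1 on
    degenerate cohorts.
    """

    name: str
    predict: Callable[[pd.DataFrame], np.ndarray]

    def __call__(self, cohort: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.predict(cohort), dtype=float)


_SAPS2_INTERCEPT = -7.7631
_SAPS2_BETA = 0.0737
_SAPS2_LOG_BETA = 0.9971


def saps2_logit(score) -> np.ndarray:
    s = np.asarray(score, dtype=float)
    return _SAPS2_INTERCEPT + _SAPS2_BETA * s + _SAPS2_LOG_BETA * np.log(s + 1.0)


def default_saps2_risk() -> RiskModel:
    """The original SAPS II hospital-mortality logistic (depends on saps2 only)."""

    def predict(cohort: pd.DataFrame) -> np.ndarray:
        logit = saps2_logit(cohort["saps2"].to_numpy())
        return 1.0 / (1.0 + np.exp(-logit))

    return RiskModel(name="saps2_logistic", predict=predict)


def empirical_stratum_risk(reference: pd.DataFrame) -> RiskModel:
    """Calibration oracle: predicted risk = observed death fraction of the
    admission's SAPS II stratum in the pooled reference cohort.

    By construction the predictions sum exactly to the observed deaths of the
    reference cohort, so the pooled SMR under this model is exactly 1.
    Querying a stratum absent from the reference raises ``KeyError``.
    """
    strata = assign_stratum(reference["saps2"].to_numpy())
    died = reference["died_in_hospital"].to_numpy(dtype=float)
    rates: dict[int, float] = {}
    for s in np.unique(strata):
        sel = strata == s
        rates[int(s)] = float(died[sel].mean())

    def predict(cohort: pd.DataFrame) -> np.ndarray:
        idx = assign_stratum(cohort["saps2"].to_numpy())
        idx = np.atleast_1d(idx)
        missing = set(int(i) for i in np.unique(idx)) - set(rates)
        if missing:
            raise KeyError(
                f"strata {sorted(missing)} have no admissions in the reference cohort"
            )
        return np.array([rates[int(i)] for i in idx], dtype=float)

    return RiskModel(name="empirical_stratum", predict=predict)


def risk_model_from_table(source: Union[str, Path, dict]) -> RiskModel:
    """Build a logit-link risk model from a coefficient table (YAML/JSON/dict).

    Expected structure::

        name: my_model
        intercept: -7.7631
        coefficients:
          saps2: 0.0737          # linear term on a cohort column
        log_coefficients:
          saps2: 0.9971          # term on ln(column + 1)

    Columns named in the table must exist in the cohort frame at predict time.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            table = yaml.safe_load(fh)
    else:
        table = dict(source)
    name = table.get("name", "custom_logit")
    intercept = float(table.get("intercept", 0.0))
    linear = {k: float(v) for k, v in (table.get("coefficients") or {}).items()}
    log_terms = {k: float(v) for k, v in (table.get("log_coefficients") or {}).items()}

    def predict(cohort: pd.DataFrame) -> np.ndarray:
        logit = np.full(len(cohort), intercept, dtype=float)
        for col, beta in linear.items():
            logit += beta * cohort[col].to_numpy(dtype=float)
        for col, beta in log_terms.items():
            logit += beta * np.log(cohort[col].to_numpy(dtype=float) + 1.0)
        return 1.0 / (1.0 + np.exp(-logit))

    return RiskModel(name=name, predict=predict)


_BUILTIN_MODELS = {"saps2_logistic": default_saps2_risk}


def get_risk_model(name_or_source) -> RiskModel:
    """Resolve a risk model by builtin name, coefficient-table path, or pass through."""
    if isinstance(name_or_source, RiskModel):
        return name_or_source
    if isinstance(name_or_source, str) and name_or_source in _BUILTIN_MODELS:
        return _BUILTIN_MODELS[name_or_source]()
    return risk_model_from_table(name_or_source)
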