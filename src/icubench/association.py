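"""Bivariable associations between unit-level factors and benchmark outcomes.

With only a handful of ICUs per registry, multivariable provider profiling
overfits; instead each a-priori structural factor (bed count, FTE
physicians-to-bed ratio, independent organization, median SAPS II, SMR) is
related to each outcome (costSRUR_LOS, costSRUR_TISS, SMR) one at a time with
a gamma-family GLM (log link).  Continuous exposures are standardized, so the
exponentiated coefficient is a relative risk per 1 SD increase; for the
binary organization factor it is the ratio vs. the "part of another
department" reference level.  Dispersion uses the Pearson-based estimator and
confidence intervals are Wald intervals on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from icubench.registry import UnitProfile, DonorPolicy

__all__ = [
    "standardize", "fit_bivariable_gamma", "build_unit_factor_table",
    "run_association_suite", "AssociationEstimate", "SmallSampleWarning",
]

CONTINUOUS_EXPOSURES = ("beds", "fte_physicians_per_bed", "median_saps2", "smr")
BINARY_EXPOSURES = ("independent_org",)
EXPOSURES = ("beds", "fte_physicians_per_bed", "independent_org", "median_saps2", "smr")
OUTCOMES = ("cost_srur_los", "cost_srur_tiss", "smr")

Z95 = 1.959963984540054  # standard normal 97.5% quantile


class SmallSampleWarning(UserWarning):
    """Emitted when a bivariable fit rests on very few units."""


@dataclass
class AssociationEstimate:
    """One bivariable relative-risk estimate with its 95% Wald interval."""

    subgroup: str
    outcome: str
    exposure: str
    relative_risk: float
    ci_low: float
    ci_high: float
    n_units: int
    converged: bool


def standardize(values) -> np.ndarray:
    """Center and scale to unit sample SD (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("standardization needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector (zero SD)")
    return (x - x.mean()) / sd


def fit_bivariable_gamma(
    rows: pd.DataFrame,
    outcome: str,
    exposure: str,
    standardize_exposure: bool = True,
    subgroup: str = "",
) -> AssociationEstimate:
    """Fit outcome ~ intercept + exposure with a gamma GLM (log link).

    Rows with a missing outcome or exposure are dropped (n_units records the
    rows actually used).  The outcome must be strictly positive.  Binary
    exposures are passed through as 0/1; continuous exposures are
    standardized unless disabled.
    """
    df = rows[[outcome, exposure]].dropna()
    n = len(df)
    if n < 3:
        raise ValueError(f"need >= 3 usable units to fit (got {n})")
    y = df[outcome].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError(f"outcome {outcome!r} must be strictly positive for a gamma model")
    x = df[exposure].to_numpy()
    if x.dtype == bool or set(np.unique(x.astype(float))) <= {0.0, 1.0}:
        xs = x.astype(float)
    elif standardize_exposure:
        xs = standardize(x)
    else:
        xs = x.astype(float)
    if n < 10:
        warnings.warn(
            f"bivariable gamma fit on only {n} units "
            f"({outcome} ~ {exposure}): estimates are fragile",
            SmallSampleWarning,
            stacklevel=2,
        )

    X = sm.add_constant(xs)
    model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect-fit / domain warnings on tiny n
        try:
            res = model.fit()  # Pearson-based scale is the Gamma default
            converged = bool(getattr(res, "converged", True))
            beta = float(res.params[1])
            se = float(res.bse[1])
        except Exception:
            return AssociationEstimate(
                subgroup=subgroup, outcome=outcome, exposure=exposure,
                relative_risk=np.nan, ci_low=np.nan, ci_high=np.nan,
                n_units=n, converged=False,
            )
    if not np.isfinite(beta) or not np.isfinite(se):
        converged = False
    return AssociationEstimate(
        subgroup=subgroup, outcome=outcome, exposure=exposure,
        relative_risk=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        n_units=n, converged=converged,
    )


def build_unit_factor_table(
    benchmark: pd.DataFrame,
    profiles: dict[str, UnitProfile],
    cohort: pd.DataFrame,
    subgroup: str,
    donor_policy: str = DonorPolicy.EXCLUDE_ALL.value,
) -> pd.DataFrame:
    """One row per unit for a subgroup: structural factors + outcomes.

    ``median_saps2`` is the unit's cohort-wide median severity (a case-mix
    factor, not subgroup-specific); outcomes come from the benchmark table at
    the requested donor policy.
    """
    sel = benchmark.loc[
        (benchmark["subgroup"] == subgroup)
        & (benchmark["donor_policy"] == donor_policy)
    ]
    if len(sel) == 0:
        return pd.DataFrame()
    wide = sel.pivot_table(
        index="unit_id", columns="measure", values="cost_srur", aggfunc="first"
    ).rename(columns={"LOS": "cost_srur_los", "TISS": "cost_srur_tiss"})
    smr = sel.groupby("unit_id")["smr"].first()
    med = cohort.groupby("unit_id")["saps2"].median()

    rows = []
    for unit_id in wide.index:
        p = profiles[unit_id]
        rows.append({
            "unit_id": unit_id,
            "beds": p.beds,
            "fte_physicians_per_bed": p.fte_physicians_per_bed,
            "independent_org": bool(p.independent_org),
            "median_saps2": float(med.get(unit_id, np.nan)),
            "smr": float(smr.get(unit_id, np.nan)),
            "cost_srur_los": float(wide.loc[unit_id].get("cost_srur_los", np.nan)),
            "cost_srur_tiss": float(wide.loc[unit_id].get("cost_srur_tiss", np.nan)),
        })
    return pd.DataFrame(rows)


def run_association_suite(
    benchmark: pd.DataFrame,
    profiles: dict[str, UnitProfile],
    cohort: pd.DataFrame,
    subgroups: Optional[tuple[str, ...]] = None,
    donor_policy: str = DonorPolicy.EXCLUDE_ALL.value,
) -> pd.DataFrame:
    """Full cross of exposures x outcomes x diagnostic subgroups.

    For each subgroup present in the benchmark table, fits every bivariable
    gamma model of {beds, FTE ratio, organization type, median SAPS II, SMR}
    against {costSRUR_LOS, costSRUR_TISS, SMR}.  Units with an undefined
    outcome are dropped from that fit, with ``n_units`` recording the rows
    used; cells with < 3 usable units are emitted unconverged with NaN
    estimates rather than silently omitted.  Deterministic given inputs.
    """
    if subgroups is None:
        subgroups = tuple(
            sg for sg in benchmark["subgroup"].unique() if sg != "ALL"
        )
    records = []
    for sg in subgroups:
        table = build_unit_factor_table(benchmark, profiles, cohort, sg, donor_policy)
        if len(table) == 0:
            continue
        for outcome in OUTCOMES:
            for exposure in EXPOSURES:
                try:
                    est = fit_bivariable_gamma(table, outcome, exposure, subgroup=sg)
                except ValueError:
                    est = AssociationEstimate(
                        subgroup=sg, outcome=outcome, exposure=exposure,
                        relative_risk=np.nan, ci_low=np.nan, ci_high=np.nan,
                        n_units=int(table[[outcome, exposure]].dropna().shape[0]),
                        converged=False,
                    )
                records.append(asdict(est))
    return pd.DataFrame.from_records(records)
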