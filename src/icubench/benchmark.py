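"""Cost-based standardized resource use ratios and standardized mortality ratios.

The core computation: unit annual direct costs are converted to
purchasing-power-parity-adjusted euros, allocated to a diagnostic subgroup by
its share of the unit's total LOS days or TISS points, and compared with the
expected cost of producing that unit's hospital survivors.  The expectation
is formed by indirect standardization: within each calendar year, the pooled
subgroup cohort is stratified by SAPS II, the expected resource use per
survivor in each stratum is the stratum's total resource divided by its
survivors, and a unit's expected cost is (survivors per stratum) x (expected
resource per survivor) x (pooled mean cost per resource unit), summed over
strata.  The ratio observed/expected is the costSRUR; SMR is observed deaths
over the sum of model-predicted death probabilities.

Conservation holds by construction: within any subgroup x measure x year the
expected costs across units sum exactly to the observed allocated costs, so
the expected-cost-weighted mean costSRUR is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from icubench.registry import (
    DonorPolicy,
    UnitProfile,
    Currency,
    subgroup as select_subgroup,
)
from icubench.severity import RiskModel, assign_stratum, default_saps2_risk, get_risk_model

__all__ = [
    "CHF_PER_EUR", "ppp_adjust", "allocate_subgroup_cost", "build_stratum_table",
    "compute_cost_srur", "compute_smr", "run_benchmark", "BenchmarkConfig",
    "unit_year_resource_totals",
]

#: Fixed exchange rate: 1.09 Swiss franc to 1.00 euro; no inflation adjustment.
CHF_PER_EUR = 1.09

_MEASURE_COLUMNS = {"LOS": "los_days", "TISS": "tiss_total"}


def ppp_adjust(amount: float, profile: UnitProfile) -> float:
    """Convert a native-currency amount to purchasing-power-parity euros.

    CHF amounts are divided by the fixed 1.09 CHF/EUR rate; the result (or a
    native EUR amount) is multiplied by the unit's PPP factor.
    """
    if amount < 0:
        raise ValueError("amount must be >= 0")
    if profile.currency is Currency.CHF:
        eur = amount / CHF_PER_EUR
    elif profile.currency is Currency.EUR:
        eur = amount
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown currency {profile.currency!r}")
    return eur * profile.ppp_factor


def allocate_subgroup_cost(
    unit_total_cost: float, subgroup_resource: float, unit_resource: float
) -> float:
    """Assign the share of a unit's direct costs proportional to the
    subgroup's share of the unit's total LOS days or TISS points."""
    if unit_resource <= 0:
        raise ValueError("unit total resource must be > 0 (degenerate unit-year)")
    if not 0 <= subgroup_resource <= unit_resource * (1 + 1e-12):
        raise ValueError("subgroup resource must lie in [0, unit total]")
    return unit_total_cost * subgroup_resource / unit_resource


def _survivor_mask(df: pd.DataFrame, count_donor_survivors: bool) -> np.ndarray:
    alive = ~df["died_in_hospital"].to_numpy(dtype=bool)
    if count_donor_survivors:
        return alive
    return alive & ~df["organ_donor"].to_numpy(dtype=bool)


def build_stratum_table(
    pooled_subgroup: pd.DataFrame,
    measure: str,
    count_donor_survivors: bool = False,
) -> pd.DataFrame:
    """Per-SAPS-II-stratum pooled resource and survivor aggregates.

    Resources are summed over all admissions in the pooled subgroup (donors
    included whenever they are present in the frame); survivors are the
    hospital survivors (donors counted only under ``count_donor_survivors``,
    i.e. the include-all donor policy).  Strata with resource but no survivors
    are merged downward into the adjacent lower occupied stratum (stratum 0
    merges upward) before the division, so that the per-survivor expectation
    is defined everywhere and total resource is conserved exactly.

    Returns a frame indexed by stratum with columns ``resource``,
    ``survivors``, ``merged_into`` (representative stratum of the merged
    block) and ``expected_per_survivor``.
    """
    if len(pooled_subgroup) == 0:
        raise ValueError("pooled subgroup is empty")
    col = _MEASURE_COLUMNS[measure]
    strata = assign_stratum(pooled_subgroup["saps2"].to_numpy())
    resource = pooled_subgroup[col].to_numpy(dtype=float)
    surv = _survivor_mask(pooled_subgroup, count_donor_survivors)

    occupied = sorted(int(s) for s in np.unique(strata))
    res = {s: float(resource[strata == s].sum()) for s in occupied}
    nsurv = {s: int(surv[strata == s].sum()) for s in occupied}
    if sum(nsurv.values()) == 0:
        raise ValueError(
            "no hospital survivors in the pooled subgroup: "
            "expected resource use per survivor is undefined"
        )

    # Merge zero-survivor strata: scan top-down, pooling into the next lower
    # occupied block; a zero-survivor bottom block pools upward.
    blocks: list[dict] = [
        {"members": [s], "resource": res[s], "survivors": nsurv[s]} for s in occupied
    ]
    i = len(blocks) - 1
    while i >= 0:
        if blocks[i]["survivors"] == 0:
            j = i - 1 if i > 0 else i + 1
            blocks[j]["members"].extend(blocks[i]["members"])
            blocks[j]["resource"] += blocks[i]["resource"]
            blocks[j]["survivors"] += blocks[i]["survivors"]
            del blocks[i]
            if i >= len(blocks):
                i = len(blocks) - 1
        else:
            i -= 1
    # An upward merge may leave block 0 empty of survivors; repeat until stable.
    while any(b["survivors"] == 0 for b in blocks):
        k = next(i for i, b in enumerate(blocks) if b["survivors"] == 0)
        j = k - 1 if k > 0 else k + 1
        blocks[j]["members"].extend(blocks[k]["members"])
        blocks[j]["resource"] += blocks[k]["resource"]
        blocks[j]["survivors"] += blocks[k]["survivors"]
        del blocks[k]

    rows = []
    for b in blocks:
        rep = min(b["members"])
        eps = b["resource"] / b["survivors"]
        for s in b["members"]:
            rows.append({
                "stratum": s,
                "resource": res[s],
                "survivors": nsurv[s],
                "merged_into": rep,
                "expected_per_survivor": eps,
            })
    table = pd.DataFrame(rows).sort_values("stratum").set_index("stratum")
    return table


def unit_year_resource_totals(admissions: pd.DataFrame) -> pd.DataFrame:
    """Total LOS days and TISS points per unit-year over *all* admissions.

    Computed on the raw (pre-exclusion) registry when available, so that the
    cohort's allocated cost share reflects its share of the ICU's entire
    activity; missing TISS values are ignored in the TISS totals.
    """
    g = admissions.groupby(["unit_id", "year"], as_index=False).agg(
        los_days=("los_days", "sum"), tiss_total=("tiss_total", "sum")
    )
    return g


def _unit_year_costs_eur(
    profiles: dict[str, UnitProfile], units: Sequence[str], years: Sequence[int]
) -> dict[tuple[str, int], float]:
    costs: dict[tuple[str, int], float] = {}
    for u in units:
        if u not in profiles:
            raise KeyError(f"no unit profile for unit {u!r}")
        p = profiles[u]
        for y in years:
            if int(y) not in p.annual_direct_costs:
                raise KeyError(f"unit {u!r} has no annual direct cost for year {y}")
            costs[(u, int(y))] = ppp_adjust(p.annual_direct_costs[int(y)], p)
    return costs


def compute_cost_srur(
    cohort: pd.DataFrame,
    profiles: dict[str, UnitProfile],
    subgroup: str,
    measure: str,
    donor_policy: Union[DonorPolicy, str] = DonorPolicy.EXCLUDE_ALL,
    unit_year_totals: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Observed and expected PPP-adjusted direct costs and costSRUR per unit.

    ``cohort`` must already reflect the donor policy (donors removed under
    the exclude-all policy, retained flagged otherwise).  Stratification,
    the expected-use reference and the pooled mean cost per resource unit are
    built per calendar year; a unit's multi-year ratio is the ratio of sums
    over years.  Units with no admissions in the subgroup are absent from the
    output; a unit with observed cost but zero expected cost is flagged
    ``expected_zero`` with an undefined (NaN) ratio.
    """
    donor_policy = DonorPolicy(donor_policy)
    if measure not in _MEASURE_COLUMNS:
        raise ValueError(f"measure must be one of {list(_MEASURE_COLUMNS)}")
    col = _MEASURE_COLUMNS[measure]
    count_donor_survivors = donor_policy is DonorPolicy.INCLUDE_ALL

    if unit_year_totals is None:
        unit_year_totals = unit_year_resource_totals(cohort)
    totals = unit_year_totals.set_index(["unit_id", "year"])[col]

    years = sorted(cohort["year"].unique())
    units = sorted(cohort["unit_id"].unique())
    costs_eur = _unit_year_costs_eur(profiles, units, years)

    acc = {
        u: {"observed_cost": 0.0, "expected_cost": 0.0,
            "n_admissions": 0, "n_survivors": 0}
        for u in units
    }
    for year in years:
        coh_y = cohort.loc[cohort["year"] == year]
        sub_y = select_subgroup(coh_y, subgroup)
        if len(sub_y) == 0:
            continue
        table = build_stratum_table(sub_y, measure, count_donor_survivors)
        eps_by_stratum = np.full(10, np.nan)
        eps_by_stratum[table.index.to_numpy()] = table["expected_per_survivor"].to_numpy()

        # observed: unit cost x subgroup share of the unit's total resource
        observed: dict[str, float] = {}
        for u, grp in sub_y.groupby("unit_id"):
            sub_res = float(grp[col].sum())
            unit_res = float(totals.loc[(u, year)])
            observed[u] = allocate_subgroup_cost(costs_eur[(u, int(year))], sub_res, unit_res)

        total_sub_resource = float(sub_y[col].sum())
        mean_cost = sum(observed.values()) / total_sub_resource

        strata = assign_stratum(sub_y["saps2"].to_numpy())
        surv = _survivor_mask(sub_y, count_donor_survivors)
        for u, grp_idx in sub_y.groupby("unit_id").indices.items():
            s_u = strata[grp_idx]
            alive_u = surv[grp_idx]
            expected_resource = float(eps_by_stratum[s_u[alive_u]].sum()) if alive_u.any() else 0.0
            acc[u]["observed_cost"] += observed[u]
            acc[u]["expected_cost"] += expected_resource * mean_cost
            acc[u]["n_admissions"] += int(len(grp_idx))
            acc[u]["n_survivors"] += int(alive_u.sum())

    rows = []
    for u in units:
        a = acc[u]
        if a["n_admissions"] == 0:
            continue
        obs, exp = a["observed_cost"], a["expected_cost"]
        if exp > 0:
            srur, flag = obs / exp, ""
        else:
            srur, flag = np.nan, "expected_zero"
        rows.append({
            "unit_id": u, "subgroup": subgroup, "measure": measure,
            "donor_policy": donor_policy.value,
            "n_admissions": a["n_admissions"], "n_survivors": a["n_survivors"],
            "observed_cost": obs, "expected_cost": exp,
            "cost_srur": srur, "flag": flag,
        })
    return pd.DataFrame(rows)


def compute_smr(
    cohort: pd.DataFrame,
    subgroup: str,
    model: Optional[RiskModel] = None,
    donor_policy: Union[DonorPolicy, str] = DonorPolicy.EXCLUDE_ALL,
) -> pd.DataFrame:
    """Observed/expected hospital mortality per unit within a subgroup.

    Expected deaths are the sum of model-predicted death probabilities.
    Donors contribute neither deaths nor predictions except under the
    include-all policy.
    """
    donor_policy = DonorPolicy(donor_policy)
    model = model if model is not None else default_saps2_risk()
    sub = select_subgroup(cohort, subgroup)
    if donor_policy is not DonorPolicy.INCLUDE_ALL:
        sub = sub.loc[~sub["organ_donor"].to_numpy(dtype=bool)].reset_index(drop=True)
    rows = []
    for u, grp in sub.groupby("unit_id"):
        observed = int(grp["died_in_hospital"].to_numpy(dtype=bool).sum())
        expected = float(model(grp).sum())
        if expected > 0:
            smr, flag = observed / expected, ""
        else:
            smr, flag = np.nan, "expected_zero"
        rows.append({
            "unit_id": u, "subgroup": subgroup, "donor_policy": donor_policy.value,
            "observed_deaths": observed, "expected_deaths": expected,
            "smr": smr, "smr_flag": flag,
        })
    return pd.DataFrame(rows)


DEFAULT_SUBGROUPS = (
    "NONTRAUMATIC_ICH", "SAH", "TBI_MULTITRAUMA", "TBI_ISOLATED",
    "NON_NEURO", "NEURO_ALL", "ALL",
)


@dataclass
class BenchmarkConfig:
    """Knobs of the end-to-end benchmarking run."""

    donor_policies: tuple[str, ...] = (
        DonorPolicy.EXCLUDE_ALL.value,
        DonorPolicy.RESOURCES_ONLY.value,
        DonorPolicy.INCLUDE_ALL.value,
    )
    subgroups: tuple[str, ...] = DEFAULT_SUBGROUPS
    measures: tuple[str, ...] = ("LOS", "TISS")
    risk_model: object = field(default="saps2_logistic")


def run_benchmark(
    admissions: pd.DataFrame,
    profiles: dict[str, UnitProfile],
    config: Optional[BenchmarkConfig] = None,
) -> pd.DataFrame:
    """Full benchmark table across subgroups x measures x donor policies.

    Takes the *raw* registry (pre-exclusion); the exclusion cascade is applied
    per donor policy, and cost-allocation denominators use every admission's
    resources.  Output is tidy: one row per unit x subgroup x measure x donor
    policy, carrying both the cost fields and the (measure-independent)
    mortality fields.  Deterministic given inputs.
    """
    from icubench.registry import apply_exclusions

    config = config or BenchmarkConfig()
    model = get_risk_model(config.risk_model)
    totals = unit_year_resource_totals(admissions)

    frames = []
    for policy in config.donor_policies:
        cohort, _ = apply_exclusions(admissions, policy)
        if len(cohort) == 0:
            continue
        for sg in config.subgroups:
            smr = compute_smr(cohort, sg, model, policy)
            if len(smr) == 0:
                continue
            for measure in config.measures:
                cost = compute_cost_srur(cohort, profiles, sg, measure, policy, totals)
                merged = cost.merge(
                    smr.drop(columns=["subgroup", "donor_policy"]),
                    on="unit_id", how="left",
                )
                frames.append(merged)
    if not frames:
        return pd.DataFrame()
    out = pd.concat(frames, ignore_index=True)
    col_order = [
        "donor_policy", "subgroup", "measure", "unit_id",
        "n_admissions", "n_survivors",
        "observed_cost", "expected_cost", "cost_srur", "flag",
        "observed_deaths", "expected_deaths", "smr", "smr_flag",
    ]
    return out[col_order]
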