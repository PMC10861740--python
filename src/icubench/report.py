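"""Descriptive summaries, report rounding rules, and run manifests.

The summary table mirrors the cost descriptives of a benchmarking report:
per diagnostic subgroup, the PPP-adjusted allocated direct costs, the mean
cost per admission, the cost per LOS day and per TISS point, and the
subgroup's share of the total direct costs — computed separately for the
LOS-based and TISS-based cost-separation schemes.

Rounding follows the presentation conventions of clinical benchmarking
reports: percentages to one decimal below 10, whole numbers above; euro
amounts to the nearest integer.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from typing import Optional, Union

import pandas as pd

from icubench.registry import UnitProfile, subgroup as select_subgroup
from icubench.benchmark import (
    ppp_adjust,
    allocate_subgroup_cost,
    unit_year_resource_totals,
)

__all__ = ["format_percent", "format_eur", "summarize", "build_manifest"]

_MEASURE_COLUMNS = {"LOS": "los_days", "TISS": "tiss_total"}

PARTITION = (
    "NONTRAUMATIC_ICH", "SAH", "TBI_MULTITRAUMA", "TBI_ISOLATED", "NON_NEURO",
)


def format_percent(numerator: float, denominator: float,
                   decimals: Optional[int] = None) -> str:
    """Render a percentage the way benchmark tables print them.

    By default values below 10% keep one decimal (e.g. ``9.3``), larger
    values are rounded to whole percent (e.g. ``22``); pass ``decimals`` to
    override.
    """
    if denominator == 0:
        raise ValueError("denominator must be nonzero")
    pct = 100.0 * numerator / denominator
    if decimals is None:
        decimals = 1 if abs(pct) < 10 else 0
    if decimals == 0:
        return f"{pct:.0f}"
    return f"{pct:.{decimals}f}"


def format_eur(amount: float) -> str:
    """Euro amounts rounded to the nearest integer, thousands-separated."""
    return f"{amount:,.0f}"


def summarize(
    cohort: pd.DataFrame,
    profiles: dict[str, UnitProfile],
    unit_year_totals: Optional[pd.DataFrame] = None,
    subgroups: tuple[str, ...] = PARTITION,
) -> pd.DataFrame:
    """Per-subgroup cost descriptives under both cost-separation schemes.

    Returns one row per subgroup x scheme with columns: n_admissions,
    total LOS days, total TISS points, allocated direct costs (EUR, PPP
    adjusted), mean cost per admission, cost per LOS day, cost per TISS
    point, and the subgroup's share of total allocated costs.  Within each
    scheme the shares over a partition of the cohort sum to 1.
    """
    if unit_year_totals is None:
        unit_year_totals = unit_year_resource_totals(cohort)
    rows = []
    for measure, col in _MEASURE_COLUMNS.items():
        totals = unit_year_totals.set_index(["unit_id", "year"])[col]
        alloc: dict[str, float] = {}
        stats: dict[str, dict] = {}
        for sg in subgroups:
            sub = select_subgroup(cohort, sg)
            cost = 0.0
            for (u, y), grp in sub.groupby(["unit_id", "year"]):
                p = profiles[u]
                unit_cost_eur = ppp_adjust(p.annual_direct_costs[int(y)], p)
                cost += allocate_subgroup_cost(
                    unit_cost_eur, float(grp[col].sum()), float(totals.loc[(u, int(y))])
                )
            alloc[sg] = cost
            stats[sg] = {
                "n_admissions": int(len(sub)),
                "total_los_days": float(sub["los_days"].sum()),
                "total_tiss_points": float(sub["tiss_total"].sum()),
            }
        grand_total = sum(alloc.values())
        for sg in subgroups:
            s = stats[sg]
            cost = alloc[sg]
            rows.append({
                "subgroup": sg,
                "scheme": measure,
                **s,
                "allocated_cost_eur": cost,
                "mean_cost_per_admission": cost / s["n_admissions"] if s["n_admissions"] else float("nan"),
                "cost_per_los_day": cost / s["total_los_days"] if s["total_los_days"] else float("nan"),
                "cost_per_tiss_point": cost / s["total_tiss_points"] if s["total_tiss_points"] else float("nan"),
                "cost_share": cost / grand_total if grand_total else float("nan"),
            })
    return pd.DataFrame(rows)


def build_manifest(
    config: Union[dict, object],
    seed: Optional[int],
    donor_policies: list[str],
    subgroups: list[str],
    output_files: list[str],
) -> dict:
    """Assemble a reproducibility manifest for one pipeline run.

    The config hash is a SHA-256 over the canonical JSON encoding, so
    identical configurations always yield identical hashes.
    """
    from icubench import __version__

    if hasattr(config, "model_dump"):
        config = config.model_dump(mode="json")
    canonical = json.dumps(config, sort_keys=True, default=str)
    return {
        "config_hash": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "donor_policies": list(donor_policies),
        "subgroups": list(subgroups),
        "versions": {"icubench": __version__, "pandas": pd.__version__},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "output_files": sorted(output_files),
    }
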