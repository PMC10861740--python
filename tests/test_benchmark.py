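"""costSRUR / SMR computation: arithmetic contracts, conservation,
oracle equivalence, invariances, donor-policy behavior, and parameter
recovery against the generator's known truth."""

import numpy as np
import pandas as pd
import pytest

from icubench.benchmark import (
    BenchmarkConfig,
    allocate_subgroup_cost,
    build_stratum_table,
    compute_cost_srur,
    compute_smr,
    ppp_adjust,
    run_benchmark,
    unit_year_resource_totals,
)
from icubench.registry import DonorPolicy, UnitProfile, apply_exclusions
from icubench.severity import empirical_stratum_risk
from icubench.synthetic import GeneratorConfig, generate_registry, inject_unit_distortion
from tests.conftest import make_admissions


def profile(unit_id="U1", cost=1_000_000.0, years=(2015,), currency="EUR", ppp=1.0):
    return UnitProfile(
        unit_id=unit_id, beds=30, fte_physicians_per_bed=0.2, independent_org=True,
        currency=currency, ppp_factor=ppp,
        annual_direct_costs={int(y): cost for y in years},
    )


def brute_force_expected_costs(cohort, profiles, measure, donor_policy="EXCLUDE_ALL"):
    """Independent per-admission oracle for the expected-cost computation.

    Plain dict-and-loop reimplementation: per calendar year, allocate costs
    admission by admission, pool stratum aggregates, merge zero-survivor
    strata downward (bottom stratum upward), and accumulate each surviving
    admission's expected contribution.
    """
    col = {"LOS": "los_days", "TISS": "tiss_total"}[measure]
    count_donor_survivors = donor_policy == "INCLUDE_ALL"
    observed, expected = {}, {}
    for year in sorted(set(cohort["year"])):
        rows = [r for _, r in cohort[cohort["year"] == year].iterrows()]
        unit_total = {}
        for r in rows:
            unit_total[r.unit_id] = unit_total.get(r.unit_id, 0.0) + r[col]
        obs_y = {}
        for u in unit_total:
            p = profiles[u]
            cost = p.annual_direct_costs[year]
            if p.currency.value == "CHF":
                cost = cost / 1.09
            cost *= p.ppp_factor
            obs_y[u] = cost  # whole cohort here is the subgroup
        # stratum aggregates
        res, surv = {}, {}
        for r in rows:
            s = min(r.saps2 // 10, 9)
            res[s] = res.get(s, 0.0) + r[col]
            alive = not r.died_in_hospital and (count_donor_survivors or not r.organ_donor)
            surv[s] = surv.get(s, 0) + (1 if alive else 0)
        # merge zero-survivor strata
        order = sorted(res)
        groups = [[s] for s in order]
        changed = True
        while changed:
            changed = False
            for i in range(len(groups) - 1, -1, -1):
                if sum(surv[s] for s in groups[i]) == 0:
                    j = i - 1 if i > 0 else i + 1
                    groups[j].extend(groups.pop(i))
                    changed = True
                    break
        eps = {}
        for g in groups:
            total_r = sum(res[s] for s in g)
            total_s = sum(surv[s] for s in g)
            for s in g:
                eps[s] = total_r / total_s
        mean_cost = sum(obs_y.values()) / sum(res.values())
        for r in rows:
            alive = not r.died_in_hospital and (count_donor_survivors or not r.organ_donor)
            if alive:
                s = min(r.saps2 // 10, 9)
                expected[r.unit_id] = expected.get(r.unit_id, 0.0) + eps[s] * mean_cost
        for u, v in obs_y.items():
            observed[u] = observed.get(u, 0.0) + v
    return observed, expected


class TestPppAdjust:
    def test_chf_fixed_rate(self):
        assert ppp_adjust(109.0, profile(currency="CHF")) == pytest.approx(100.0)

    def test_eur_identity_and_ppp_scaling(self):
        assert ppp_adjust(100.0, profile()) == 100.0
        assert ppp_adjust(100.0, profile(ppp=0.9)) == pytest.approx(90.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ppp_adjust(-1.0, profile())


class TestAllocation:
    def test_proportional_share(self):
        assert allocate_subgroup_cost(1_000_000, 25, 100) == pytest.approx(250_000)

    def test_identity_and_zero(self):
        assert allocate_subgroup_cost(5e5, 80, 80) == pytest.approx(5e5)
        assert allocate_subgroup_cost(5e5, 0, 80) == 0.0

    def test_degenerate_unit_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            allocate_subgroup_cost(5e5, 0, 0)


class TestStratumTable:
    def test_expected_per_survivor_definition(self):
        cohort = make_admissions(
            [{"saps2": 32, "los_days": 3.0, "died_in_hospital": False}] * 10
        )
        table = build_stratum_table(cohort, "LOS")
        assert table.loc[3, "expected_per_survivor"] == pytest.approx(3.0)

    def test_zero_survivor_stratum_merges_downward(self):
        rows = [
            {"saps2": 85, "tiss_total": 8.8, "died_in_hospital": False}
            for _ in range(10)
        ] + [
            {"saps2": 95, "tiss_total": 6.0, "died_in_hospital": True},
            {"saps2": 95, "tiss_total": 6.0, "died_in_hospital": True},
        ]
        table = build_stratum_table(make_admissions(rows), "TISS")
        # stratum 9 (12 points, 0 survivors) pools into stratum 8 (88 points, 10)
        assert table.loc[9, "merged_into"] == 8
        assert table.loc[9, "expected_per_survivor"] == pytest.approx(10.0)
        assert table.loc[8, "expected_per_survivor"] == pytest.approx(10.0)

    def test_bottom_stratum_merges_upward(self):
        rows = [
            {"saps2": 5, "los_days": 4.0, "died_in_hospital": True},
            {"saps2": 15, "los_days": 2.0, "died_in_hospital": False},
        ]
        table = build_stratum_table(make_admissions(rows), "LOS")
        assert table.loc[0, "merged_into"] == 0
        assert table.loc[0, "expected_per_survivor"] == pytest.approx(6.0)

    def test_total_resource_conserved(self, small_registry):
        _, admissions, _, _ = small_registry
        cohort, _ = apply_exclusions(admissions)
        table = build_stratum_table(cohort, "LOS")
        assert table["resource"].sum() == pytest.approx(
            cohort["los_days"].sum(), rel=1e-12
        )

    def test_all_dead_subgroup_rejected(self):
        cohort = make_admissions([{"died_in_hospital": True}] * 4)
        with pytest.raises(ValueError, match="survivor"):
            build_stratum_table(cohort, "LOS")


class TestCostSrur:
    def test_single_unit_is_its_own_reference(self):
        cohort = make_admissions([
            {"saps2": s, "los_days": l, "tiss_total": 40 * l, "died_in_hospital": d}
            for s, l, d in [(10, 1.0, False), (35, 4.0, False), (35, 2.0, True), (62, 9.0, False)]
        ])
        profiles = {"U1": profile()}
        for measure in ("LOS", "TISS"):
            out = compute_cost_srur(cohort, profiles, "ALL", measure)
            assert out["cost_srur"].iloc[0] == pytest.approx(1.0, rel=1e-12)

    def test_conservation_and_weighted_mean_one(self, small_registry):
        _, admissions, profiles, _ = small_registry
        cohort, _ = apply_exclusions(admissions)
        totals = unit_year_resource_totals(admissions)
        for sg in ("ALL", "NEURO_ALL", "NONTRAUMATIC_ICH"):
            for measure in ("LOS", "TISS"):
                out = compute_cost_srur(cohort, profiles, sg, measure,
                                        unit_year_totals=totals)
                assert out["observed_cost"].sum() == pytest.approx(
                    out["expected_cost"].sum(), rel=1e-9
                )
                wmean = (out["cost_srur"] * out["expected_cost"]).sum() / out["expected_cost"].sum()
                assert wmean == pytest.approx(1.0, rel=1e-9)

    def test_brute_force_oracle_equivalence_single_cohort(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(150):
            rows.append({
                "unit_id": f"U{rng.integers(1, 4)}",
                "year": int(rng.choice([2015, 2016])),
                "saps2": int(rng.integers(0, 110)),
                "los_days": float(rng.exponential(3.0) + 0.1),
                "tiss_total": float(rng.exponential(100.0) + 1),
                "died_in_hospital": bool(rng.random() < 0.35),
            })
        cohort = make_admissions(rows)
        profiles = {
            u: profile(u, cost=float(rng.uniform(5e5, 2e6)), years=(2015, 2016))
            for u in ["U1", "U2", "U3"]
        }
        for measure in ("LOS", "TISS"):
            out = compute_cost_srur(cohort, profiles, "ALL", measure).set_index("unit_id")
            obs, exp = brute_force_expected_costs(cohort, profiles, measure)
            for u in obs:
                assert out.loc[u, "observed_cost"] == pytest.approx(obs[u], rel=1e-9)
                assert out.loc[u, "expected_cost"] == pytest.approx(exp[u], rel=1e-9)

    def test_scale_invariance_of_costs(self, small_registry):
        _, admissions, profiles, _ = small_registry
        cohort, _ = apply_exclusions(admissions)
        totals = unit_year_resource_totals(admissions)
        base = compute_cost_srur(cohort, profiles, "ALL", "LOS", unit_year_totals=totals)
        scaled_profiles = {
            u: p.model_copy(update={
                "annual_direct_costs": {y: 7.3 * c for y, c in p.annual_direct_costs.items()}
            })
            for u, p in profiles.items()
        }
        scaled = compute_cost_srur(cohort, scaled_profiles, "ALL", "LOS",
                                   unit_year_totals=totals)
        np.testing.assert_allclose(
            base["cost_srur"].to_numpy(), scaled["cost_srur"].to_numpy(), rtol=1e-12
        )

    def test_measure_coherence_when_tiss_proportional_to_los(self, small_registry):
        _, admissions, profiles, _ = small_registry
        cohort, _ = apply_exclusions(admissions)
        cohort = cohort.assign(tiss_total=cohort["los_days"] * 41.7)
        totals = unit_year_resource_totals(cohort)
        los = compute_cost_srur(cohort, profiles, "ALL", "LOS", unit_year_totals=totals)
        tiss = compute_cost_srur(cohort, profiles, "ALL", "TISS", unit_year_totals=totals)
        np.testing.assert_allclose(
            los["cost_srur"].to_numpy(), tiss["cost_srur"].to_numpy(), rtol=1e-9
        )

    def test_unit_with_no_survivors_flagged_not_infinite(self):
        rows = [{"unit_id": "U1", "saps2": 30, "died_in_hospital": True}] * 3
        rows += [{"unit_id": "U2", "saps2": 30, "died_in_hospital": False}] * 3
        cohort = make_admissions(rows)
        profiles = {"U1": profile("U1"), "U2": profile("U2")}
        out = compute_cost_srur(cohort, profiles, "ALL", "LOS").set_index("unit_id")
        assert out.loc["U1", "flag"] == "expected_zero"
        assert np.isnan(out.loc["U1", "cost_srur"])
        assert np.isfinite(out.loc["U2", "cost_srur"])

    def test_two_statistically_identical_units_near_parity(self):
        cfg = GeneratorConfig(seed=21, n_units=2, admissions_per_unit_year=1700)
        admissions, profiles, _ = generate_registry(cfg)
        cohort, _ = apply_exclusions(admissions)
        totals = unit_year_resource_totals(admissions)
        for measure in ("LOS", "TISS"):
            out = compute_cost_srur(cohort, profiles, "ALL", measure,
                                    unit_year_totals=totals)
            assert out["cost_srur"].between(0.9, 1.1).all()


class TestSmr:
    def test_pooled_smr_is_one_under_empirical_model(self, small_registry):
        _, admissions, _, _ = small_registry
        cohort, _ = apply_exclusions(admissions)
        model = empirical_stratum_risk(cohort)
        out = compute_smr(cohort, "ALL", model)
        pooled = out["observed_deaths"].sum() / out["expected_deaths"].sum()
        assert pooled == pytest.approx(1.0, rel=1e-9)

    def test_zero_observed_deaths_gives_zero(self):
        cohort = make_admissions([{"unit_id": "U1"}, {"unit_id": "U1", "saps2": 70}])
        out = compute_smr(cohort, "ALL")
        assert out["smr"].iloc[0] == 0.0

    def test_donors_excluded_from_both_sides_unless_included(self):
        rows = [{"unit_id": "U1", "saps2": 60, "died_in_hospital": True,
                 "organ_donor": True}] + [{"unit_id": "U1"}] * 4
        cohort = make_admissions(rows)
        excl = compute_smr(cohort, "ALL", donor_policy="RESOURCES_ONLY")
        incl = compute_smr(cohort, "ALL", donor_policy="INCLUDE_ALL")
        assert excl["observed_deaths"].iloc[0] == 0
        assert incl["observed_deaths"].iloc[0] == 1
        assert incl["expected_deaths"].iloc[0] > excl["expected_deaths"].iloc[0]


class TestRunBenchmark:
    def test_tidy_output_and_determinism(self, small_registry):
        _, admissions, profiles, _ = small_registry
        cfg = BenchmarkConfig(subgroups=("ALL", "NEURO_ALL"))
        out1 = run_benchmark(admissions, profiles, cfg)
        out2 = run_benchmark(admissions, profiles, cfg)
        pd.testing.assert_frame_equal(out1, out2)
        assert set(out1["donor_policy"]) == {
            "EXCLUDE_ALL", "RESOURCES_ONLY", "INCLUDE_ALL"
        }
        assert set(out1["measure"]) == {"LOS", "TISS"}

    def test_empty_subgroup_cell_absent_run_continues(self):
        rows = [{"unit_id": "U1", "diagnosis_group": "SAH"},
                {"unit_id": "U1", "diagnosis_group": "OTHER"},
                {"unit_id": "U2", "diagnosis_group": "OTHER"}]
        admissions = make_admissions(rows)
        profiles = {"U1": profile("U1"), "U2": profile("U2")}
        cfg = BenchmarkConfig(donor_policies=("EXCLUDE_ALL",), subgroups=("SAH", "ALL"))
        out = run_benchmark(admissions, profiles, cfg)
        sah_units = set(out.loc[out["subgroup"] == "SAH", "unit_id"])
        assert sah_units == {"U1"}
        assert set(out.loc[out["subgroup"] == "ALL", "unit_id"]) == {"U1", "U2"}

    def test_donor_policy_noop_without_donors(self, small_registry):
        _, admissions, profiles, _ = small_registry
        no_donors = admissions.loc[~admissions["organ_donor"]].reset_index(drop=True)
        cfg_a = BenchmarkConfig(donor_policies=("EXCLUDE_ALL",), subgroups=("ALL",))
        cfg_b = BenchmarkConfig(donor_policies=("INCLUDE_ALL",), subgroups=("ALL",))
        a = run_benchmark(no_donors, profiles, cfg_a).drop(columns="donor_policy")
        b = run_benchmark(no_donors, profiles, cfg_b).drop(columns="donor_policy")
        pd.testing.assert_frame_equal(a, b)

    def test_resources_only_raises_srur_of_donor_hosting_unit(self):
        # donors with large stays hosted by U1 only
        rows = []
        for u in ("U1", "U2"):
            rows += [{"unit_id": u, "saps2": 40, "los_days": 2.0,
                      "died_in_hospital": False}] * 5
            rows += [{"unit_id": u, "saps2": 40, "los_days": 1.0,
                      "died_in_hospital": True}]
        rows += [{"unit_id": "U1", "saps2": 42, "los_days": 8.0,
                  "died_in_hospital": True, "organ_donor": True}] * 2
        admissions = make_admissions(rows)
        profiles = {"U1": profile("U1"), "U2": profile("U2")}
        cfg = BenchmarkConfig(donor_policies=("EXCLUDE_ALL", "RESOURCES_ONLY"),
                              subgroups=("ALL",), measures=("LOS",))
        out = run_benchmark(admissions, profiles, cfg)
        u1 = out[out["unit_id"] == "U1"].set_index("donor_policy")["cost_srur"]
        assert u1["RESOURCES_ONLY"] >= u1["EXCLUDE_ALL"]


class TestParameterRecovery:
    """Recovery of injected unit distortions against the generator truth."""

    def test_cost_inflation_recovered_with_pooled_reference_shrinkage(self):
        # one of six equal units inflated x1.5: the pooled reference absorbs
        # 1/6 of the excess, so the estimand is 1.5 / (1 + 0.5/6) = 1.3846
        srurs = []
        for seed in (101, 102, 103):
            cfg = inject_unit_distortion(
                GeneratorConfig(seed=seed, admissions_per_unit_year=1000),
                "U3", cost_inflation=1.5,
            )
            admissions, profiles, _ = generate_registry(cfg)
            cohort, _ = apply_exclusions(admissions)
            out = compute_cost_srur(cohort, profiles, "ALL", "LOS",
                                    unit_year_totals=unit_year_resource_totals(admissions))
            srurs.append(float(out.set_index("unit_id").loc["U3", "cost_srur"]))
        assert np.mean(srurs) == pytest.approx(1.5 / (1 + 0.5 / 6), abs=0.08)

    def test_mortality_odds_recovered_at_attenuated_truth(self):
        # doubling each admission's death odds multiplies its probability by
        # 2/(1+p); the implied SMR truth is sum(2p/(1+p))/sum(p), computed
        # here directly from the generator's own risk law
        cfg = inject_unit_distortion(
            GeneratorConfig(seed=104, admissions_per_unit_year=1700),
            "U2", mortality_odds=2.0,
        )
        admissions, profiles, _ = generate_registry(cfg)
        cohort, _ = apply_exclusions(admissions)
        model = cfg.implied_risk_model()
        out = compute_smr(cohort, "ALL", model).set_index("unit_id")
        u2 = cohort[cohort["unit_id"] == "U2"]
        p = model(u2)
        truth = float((2 * p / (1 + p)).sum() / p.sum())
        assert out.loc["U2", "smr"] == pytest.approx(truth, rel=0.10)
        others = out.drop("U2")["smr"]
        assert ((others > 0.85) & (others < 1.15)).all()
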