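# Methods

## The benchmarking problem

An ICU's raw cost per admission or raw mortality says little about its
performance: units differ in case mix, and sicker patients cost more and die
more often. Indirect standardization answers the counterfactual question
"what would this unit's totals be if it performed like the pooled network on
its own patients?" for two dimensions at once — resource use needed to
produce hospital survivors (costSRUR) and hospital mortality (SMR).

## Cohort definition

The analysis cohort contains emergency, first-time ICU admissions with known
hospital discharge status and non-missing TISS, sex and GCS. The exclusion
cascade runs in a fixed order (ICU-to-ICU transfer, non-emergency, unknown
discharge status, readmission, missing TISS, missing sex, missing GCS,
organ donor) and records the first matching reason per excluded admission,
so a flow-chart style accounting is reproducible: every input admission ends
up in exactly one of cohort or exclusion log.

Potential organ donors are a special population: by admission intent their
hospital mortality is ~100%, above anything a severity score predicts. Three
policies are implemented: `EXCLUDE_ALL` (primary; donors removed from
resources and outcomes), `RESOURCES_ONLY` (donor stays and TISS counted in
observed costs and in the pooled reference, donors never counted as
survivors nor in the mortality tallies), `INCLUDE_ALL` (donors are ordinary
admissions). `RESOURCES_ONLY` is represented by a retained-but-flagged
record rather than row duplication, so one cohort object serves all
downstream variants.

## costSRUR

Within each calendar year and diagnostic subgroup:

1. **Currency.** Unit annual direct costs (salaries, drugs, fluids,
   disposables) are converted at a fixed 1.09 CHF/EUR, without inflation
   adjustment, and multiplied by the unit's purchasing-power-parity factor
   (default 1.0; configurable per unit).
2. **Allocation.** The subgroup's observed cost in a unit is the unit's
   annual cost times the subgroup's share of the unit's *total* resource
   (over all admissions of that unit-year, not just the cohort) — measured
   as LOS days for costSRUR_LOS and TISS points for costSRUR_TISS.
3. **Reference.** Admissions are binned by SAPS II into strata 0–9, 10–19,
   …, 80–89, ≥90. The expected resource per survivor in stratum *s* is the
   pooled subgroup's resource total divided by its survivor count. Strata
   with resource but no survivors are merged downward into the adjacent
   lower occupied stratum (a survivor-free bottom stratum merges upward)
   before the division — this keeps the expectation defined everywhere and
   conserves total resource exactly.
4. **Expectation.** The pooled mean cost per resource unit is the allocated
   subgroup cost over all units divided by the subgroup resource total
   (subgroup-pooled, not per-unit — per-unit means would break
   conservation). A unit's expected cost is
   Σ_s survivors(unit, s) × expected-per-survivor(s) × mean-cost.
5. **Ratio.** costSRUR = observed/expected, with yearly observed and
   expected sums accumulated over the study window before the ratio (ratio
   of sums, not mean of ratios — this preserves the conservation identity
   across years).

Conservation is an exact algebraic identity of this construction: within
any subgroup × measure × donor policy, Σ_units expected = Σ_units observed,
hence the expected-cost-weighted mean costSRUR is exactly 1. The test suite
verifies it to 1e-9 relative and checks the whole expectation against an
independent per-admission brute-force loop on random small cohorts.

Degenerate cells are surfaced, never silently infinite: a unit with
observed cost but zero expected cost (no survivors) carries a NaN ratio and
an `expected_zero` flag; a unit with no admissions in a subgroup is absent
from that table.

## SMR

SMR = observed hospital deaths / Σ predicted death probabilities, per unit
and subgroup. Risk models are pluggable (`RiskModel`): the default is the
original published SAPS II logistic; arbitrary coefficient tables (logit
link, linear and ln(x+1) terms on cohort columns) can be loaded from
YAML/JSON; and `empirical_stratum_risk` predicts each admission's pooled
stratum death rate, which makes the pooled SMR exactly 1 — the calibration
oracle used throughout the tests. Consortium-customized mortality models
have unpublished coefficients, which is why the interface is pluggable
rather than hard-coded.

## Bivariable unit-factor models

With a handful of units, multivariable provider profiling overfits, so each
structural factor is related to each outcome one at a time: gamma GLM with
log link, intercept plus a single exposure, dispersion by the Pearson-based
estimator, Wald 95% intervals on the log scale, exponentiated to relative
risks. Continuous exposures are standardized (centered, per 1 sample-SD
increase, n−1 denominator); the binary organization factor is coded with
"part of another department" as reference. Fits on fewer than 10 units emit
an explicit `SmallSampleWarning`; fewer than 3 usable units yields no
estimate. Units with an undefined outcome are dropped from that fit with
`n_units` recording the rows actually used. The full suite crosses
{beds, FTE physicians/bed, independent organization, median SAPS II, SMR} ×
{costSRUR_LOS, costSRUR_TISS, SMR} × {four neurosurgical diagnoses,
non-neurosurgical, combined neurosurgical}; the SMR-on-SMR cell is
tautological but kept so the table's cardinality is predictable.

Simulation checks: the log-coefficient of a known gamma-mean effect
(0.3 per SD, shape 10, 200 units) is recovered within ±0.1 in ≥9/10 seeds,
and the Wald interval covers a null effect in 92–98% of replicates.

## The synthetic registry generator

Defaults emulate a six-unit, three-year university-hospital cohort of
emergency admissions (1,575 admissions per unit-year ≈ 28,350 total):

- **Case mix:** 22% neurosurgical, split 41/23/13/23 between nontraumatic
  ICH, SAH, multitrauma TBI and isolated TBI.
- **Severity:** per-group SAPS II as a discretized gamma whose shape is
  solved from the published relative IQR and whose scale pins the published
  median exactly (34/28/31/29/36 for ICH/SAH/MT-TBI/iso-TBI/other).
- **GCS:** a monotone decreasing map of SAPS II plus Gaussian noise,
  clipped to 3–15.
- **Mortality:** SAPS II logistic with per-group calibration intercepts
  (−1.37/−1.51/−2.28/−1.87/−1.59) fitted once at n = 360,000 so each group
  reproduces its published hospital-mortality rate (11.2/10.6/6.5/6.4/12.6%)
  — the original 1993 equation roughly doubles modern mortality, which is
  why benchmarking consortia recalibrate. `GeneratorConfig.implied_risk_model()`
  exposes this law as a `RiskModel`, the correct reference for SMR analyses
  of synthetic data.
- **Stay:** log-normal log-LOS with group medians pinned to the published
  values (1.7/3.4/2.3/1.5/1.5 days), a mild severity link (+0.02 per SAPS II
  point, so the cost per survivor rises across strata), a −0.45 location
  shift for nonsurvivors (needed so the per-survivor reference is
  non-trivial), and group log-SDs (1.28/1.01/1.26/1.25/1.24) solved by
  simulation so each group's *mean* stay reproduces its published mean
  direct cost per admission at the pooled cost level — a two-parameter
  log-normal cannot pin median, IQR and mean at once, and the mean drives
  the cost structure, so it wins over the IQR. The ICH mean cost is not
  published and is interpolated just above isolated TBI, preserving the
  published ordering.
- **Workload:** TISS total = LOS × a per-day rate (38 points/day, ±25%
  log-normal noise) with a severity loading (+30% at twice the median
  severity).
- **Costs:** annual unit cost = 1,985 EUR per LOS-day × the unit-year's
  total LOS × 2% log-normal noise; homogeneous cost levels across units by
  default (published pooled costs per LOS-day are nearly constant across
  subgroups), with per-unit heterogeneity available via
  `unit_cost_level_log_sd`. The last unit bills in CHF at 1.09/EUR, so the
  currency path is always exercised.
- **Special populations:** 1.1% potential organ donors (severity shifted
  up, death forced, stays halved) and small fractions of transfers,
  electives, readmissions, unknown outcomes and missing fields that feed
  the exclusion cascade.
- **Unit structure:** beds uniform on 21–45, FTE physicians/bed uniform on
  0.12–0.35, four of six units independently organized.

Reproducibility: every unit-year draws from its own `SeedSequence` spawned
from the config seed, so output is byte-identical under a seed and units
are statistically independent. `inject_unit_distortion` scales one unit's
per-admission resource accrual (LOS, hence TISS and costs) or death odds
and records the injection in a truth record.

**What the generator does not emulate:** within-admission time structure
(daily TISS), correlated unit-level practice styles, case-mix drift over
years, coding differences between units, or the real cohort's joint
distributions beyond the published marginals. Passing recovery tests
therefore demonstrate that the estimators recover known distortions under
the assumed structure, not that any particular real unit is mis-profiled.

### Recovery estimands are not the raw injection factors

Two attenuation effects are intrinsic to the method and documented here
because they set the recovery targets:

- *Pooled-reference shrinkage:* the distorted unit participates in its own
  reference. With one of six equal units inflated ×k, the costSRUR estimand
  is k/(1+(k−1)/6) — 1.385 for k = 1.5.
- *Odds-to-probability attenuation:* multiplying death odds by f scales
  each probability by f/(1+(f−1)p), so the implied SMR truth is
  Σ f·p/(1+(f−1)p) / Σ p. Under this case mix (pooled mortality ~12%, with
  expected deaths concentrated in high-risk admissions) doubling the odds
  yields an SMR truth of ≈1.47, and no probability law matching the
  published pooled mortality can push a doubled-odds unit's SMR to 2
  (the flat-law upper bound is 2/1.122 ≈ 1.78). The estimator is unbiased
  for the attenuated truth, which the tests verify directly.

## Numerical choices

- Stratum merging as described above; merging is stable and conservation-
  preserving by construction.
- Undefined ratios are NaN plus a flag column, never ±inf.
- Exclusion precedence is the fixed order listed; idempotent on filtered
  cohorts.
- Gamma GLM fitting via iteratively reweighted least squares (statsmodels),
  Pearson-based dispersion; non-convergence and degenerate designs are
  flagged (`converged=False`), not silently estimated.
- Report rounding: percentages to one decimal below 10%, whole percent
  above; euro amounts to the nearest integer.
- Problem sizes in the test suite: conservation and coherence run on a
  6 × 3 × 2,000 registry; recovery runs use 10 seeds at ~5,100 admissions
  per unit; the coverage simulation uses 250 replicates of 200 units; the
  brute-force oracle comparison uses 100 random cohorts of ≤200 admissions.

## Known limitations

- The default SAPS II logistic is a stand-in for consortium-customized
  mortality models whose coefficients are not public; absolute SMR levels
  computed with it on modern data will sit well below 1. Use a custom
  coefficient table or the empirical stratum model when calibration
  matters.
- Bivariable estimates on six units are fragile by construction (hence the
  explicit warning); the suite validates the machinery on simulated
  many-unit networks.
- Cost allocation assumes direct costs scale with LOS/TISS within a
  unit-year; fixed-cost structures (standby capacity) are not modeled.
- Diagnosis grouping must be pre-assigned in the input; mapping from native
  coding systems is out of scope.
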