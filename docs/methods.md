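# Methods

## Model structure

The engine (`cariescea.markov_engine`) propagates a closed cohort —
fractional expected persons, not microsimulated individuals — through four
mutually exclusive states (caries-free, caries, edentulous, dead) in
one-year cycles. Within a cycle, mortality applies first to all alive
states; surviving caries-free children then develop a new case with the
(possibly intervention-adjusted) per-person probability. Dead is absorbing.
Edentulism is retained for structural fidelity but has zero inflow at every
modelled age (it only arises from age 20+), and carries no costs or
disutility.

Two caries dwell-time policies are supported because the episodic valuation
does not pin one down:

- `one_cycle` (default): an incident case occupies the caries state for one
  cycle and returns to caries-free (the tooth is treated or arrested; the
  episode, not the occupancy, carries the value);
- `absorbing`: cases remain in the caries state.

All value accrual is **event-based**: incident cases carry their decayed
teeth, episode DALYs/QALYs and per-case costs in the cycle they occur.
Within-cycle correction (half-cycle/trapezoid averaging of start- and
end-of-cycle occupancy, selectable vs `none`) therefore affects only
occupancy-derived outputs such as alive person-years; this matches the view
that transitions happen throughout a cycle while events are counted when
they happen. Discounting is `1/(1+r)^t` with cycle 0 undiscounted and
r = 3%/year for both costs and outcomes.

Multiple cases per child per year are excluded: incidence is a per-person
probability (a 0.10 dmft increment read as 10 new affected individuals per
100), and decayed-tooth counts come from the 1.64 teeth-per-case multiplier
rather than repeat transitions. Cohorts spanning several start ages (ages
6–12 for the varnish programs; 6 and 12 for sealants) split the enrolled
count evenly across start ages, since per-age enrolment counts are not part
of the inputs; each single-age track runs independently and the traces sum.
The 6-month start age of the anticipatory-guidance cohort maps onto the
cycle grid as ages 0.5, 1.5, … with interpolation into the integer-age
schedules.

## Episode valuation

A case is a 28-day symptomatic episode. With toothache probability
*s* — published only as the range 8.4–21.0%, so stored as a resolvable
range with mid-range default 0.147 — one case accrues

- DALYs: `0.010 x s x 28/365 ≈ 1.13e-4` (disability weight 0.010, SD 0.004),
- QALYs forgone: `0.05 x s x 28/365 ≈ 5.64e-4`, where 0.05 is half of the
  decrement from the caries health-state utility 0.9 (SD 0.120 on the
  utility) — halved deliberately because a caries-free child is not in
  perfect health.

The per-case QALY:DALY ratio is therefore exactly
`utility_gain / disability_weight = 5` whenever both use the same episode
model. There is no years-of-life-lost term and no edentulism valuation.

Treatment cost per case is
`access x (54.69 + 1.64 x 189.61) ≈ access x 365.65` AUD. The access
probability — the fraction of cases that actually incur check-up and
restoration costs — is never published; the default 0.10 was calibrated
once so that healthcare-cost offsets are a small fraction of program costs,
consistent with the published incremental costs being close to the
discounted program costs for every arm, and plausibly reflects low dental
service uptake among low-income children. It is an explicit, configurable
parameter.

The widened-cost scenario adds, per case, a 15%/85% public/private-weighted
yearly fee for other caries-related items (illustrative defaults AUD$120
public / AUD$180 private; the exact published item schedule is not in the
main text), plus hospitalisation (AUD$2,700, an order-of-magnitude figure
for a dental extraction-and-restoration admission) and dental general
anaesthesia (AUD$1,050) for children under 7 experiencing toothache — the
hospitalisation component only in the anticipatory-guidance models, where
the underlying trial data apply.

## Interventions

Effect transforms are isolated one-per-mechanism so alternatives can be
swapped:

- **Anticipatory guidance (1a/1b)**: the trial effect is a cumulative mean
  dmft difference (−0.15 home visits, −0.18 telehealth) over the 6-year
  window. It converts to a flat per-cycle case-probability reduction
  `|Δdmft| / teeth_per_case / window`, applied to deciduous incidence only
  and floored at zero incidence. The conversion divides by the (sampled)
  teeth-per-case, which makes prevented *teeth* insensitive to that draw
  while prevented *cases* vary — an acknowledged consequence of converting
  a tooth-level effect to case counts.
- **Fluoride varnish (2a/2b)**: preventive fractions 0.37 (deciduous) and
  0.43 (permanent) multiply the respective incidence rates; both delivery
  arms share the identical effect stream and differ only in cost (2b pays
  76.9% of the varnish fee and no screening).
- **Fissure sealants (3)**: the 0.12 odds ratio converts occlusal-molar
  risk via `or·p/(1−p+or·p)` and applies only to the occlusal-molar share
  of permanent incidence; non-occlusal and deciduous risk is untouched.

Effectiveness applies at 100% for every cycle of the effect window (decay
rate 0); under the 12-year extrapolation it applies to all 12 cycles while
the cost schedules stay fixed at their original 6- or 2-year windows.

Cost schedules reproduce the published per-child arithmetic: 11 home or
telehealth visits (1 in year 0, then 2/year) at AUD$23.33 + AUD$12.34
travel (home) or AUD$16.04 (telehealth); screening AUD$29.25 first visit
plus two AUD$36.80 varnish visits per year; screening plus four AUD$49.00
sealants in a single first-year visit. Travel costs for the school
programs are excluded (no reliable per-child estimate). The one published
program-cost cell that disagrees with its own fee arithmetic (varnish-2a
first year, 34.6 vs 34.3 million) is stored on the spec as a reported
override; computation always uses the formula.

## Synthetic epidemiology

The generator emulates the statistical structure of the real inputs, not
their values:

- **Incidence**: `base_rate x age curve x lognormal noise`, clipped to
  [0, 1]; the age curve declines linearly from ~1.25 at birth to a floor of
  0.3 by the late teens (caries onset risk peaks in early childhood). The
  low-income schedule is `min(1, general x ratio)`. Defaults
  `base_rate = 0.15`, `ratio = 1.5`, `noise_sd = 0.1` put low-income
  incidence around 0.15–0.3/year at the modelled ages — the magnitude at
  which prevented-case counts are the same order as the published
  incremental effects.
- **Dentition split**: deciduous share 1.0 up to age 5 declining linearly
  to 0.0 at age 14.
- **Occlusal-molar share**: 0.25 of permanent incidence by default. The
  occlusal surfaces of the four molars sealed in one round are a minority
  of whole-dentition permanent risk; 0.25 also keeps the sealant program
  the least cost-effective intervention under the default calibration, the
  ordering the qualitative result requires. It is configurable, and the
  sealant result is sensitive to it.
- **Mortality**: female rate `1 − (1 − level)^(shape x noise)` with a
  U-ish shape (infant peak, mid-childhood dip, mild adolescent rise),
  male rate via a fixed 1.35 hazard ratio on the survival scale, cohort
  51.2% male with sex-shared incidence. Default level 3e-4/year; at these
  magnitudes mortality is almost irrelevant to the results, which is
  faithful to child cohorts.

What passing tests on synthetic schedules do **not** show: agreement with
real national incidence levels, real low-income gradients, or real per-age
cohort sizes. Quantities that depend on those (absolute prevented teeth,
absolute incremental costs) are order-of-magnitude reproductions only; the
qualitative conclusions (0% cost-effectiveness probability at the stated
thresholds, the cost-per-DT ranking) are robust to the calibration because
the ICERs exceed the thresholds by ~2 orders of magnitude.

## Probabilistic sensitivity analysis

2,000 Monte Carlo iterations by default ("cycles" in the source analysis's
tooling vocabulary; distinct from Markov cycles). Each iteration draws one
parameter vector — normal distributions truncated by resampling — and runs
both arms on it (common random numbers; switchable only by running arms
with separate draws yourself):

| parameter | distribution | truncation |
|---|---|---|
| Δdmft (1a/1b) | N(−0.15/−0.18, 25% of mean) | ≤ 0 |
| PF deciduous/permanent | N(0.37/0.43, 0.07) | [0, 1] |
| odds ratio (3) | N(0.12, 0.03) | > 0 |
| disability weight | N(0.010, 0.004) | ≥ 0 |
| baseline utility | N(0.9, 0.120) | [0, 1] |
| teeth per case | N(1.64, 1.262) | > 0 |
| check-up / restoration / travel fee | N(mean, published SD) | ≥ 0 |

Effect-size SDs are not published (the source derived them in proprietary
software from trial data); the values above are this package's choices: a
25% coefficient of variation for the crude trial differences, and SDs of
the order of the meta-analytic interval half-widths for PF and OR. The
toothache fraction is held at its resolved value (a range, not a
distribution, is published). Draws are keyed by `(seed, iteration)` via
numpy's `default_rng` seed sequences, so any iteration is reproducible in
isolation.

Summaries: means and standard errors (`sd/sqrt(n)`) of incremental cost,
DT, DALYs, QALYs; ICERs as ratios of means with explicit
dominant/dominated/undefined markers (zero incremental effect is flagged,
never raised); cost-effectiveness probability as the share of iterations
with `WTP x Δeffect − Δcost > 0`; league table ranked by AUD per DT
prevented ascending (dominant first, undefined last, ties broken by
incremental cost).

## Numerical choices and degenerate inputs

- Expected-value propagation is exact linear algebra on 4-vectors; mass
  conservation is asserted at every cycle to 1e-6 relative.
- Truncated sampling uses rejection with a 1,000-try cap, falling back to
  the clipped mean for pathological bounds; an SD of 0 short-circuits to
  the mean, collapsing the PSA onto the deterministic run (SE 0).
- Degenerate generator inputs (all-zero or saturated incidence) warn rather
  than fail; an anticipatory-guidance reduction exceeding baseline
  incidence clips to zero incidence and logs a warning (once per
  intervention per process).
- Config files are YAML with unit-suffixed keys; loading re-runs every
  invariant and names the offending field. Schedule coverage of
  `[min start age, max start age + horizon]` is enforced at construction.

## Problem sizes

The test suite runs the full five-intervention PSA at 500 iterations
(ranking and probability checks) and the acceptance script at the full
2,000; engine-versus-oracle comparisons use cohorts of 1,000 over 2–6
cycles. A 2,000-iteration, five-intervention run completes in well under a
minute on one core.

## Known limitations

- dmft/DMFT increments are a proxy for caries; converting a tooth-level
  trial effect to case probabilities via teeth-per-case is a modelling
  choice, isolated but influential for the anticipatory-guidance arms.
- The synthetic calibration is structural, not fitted; absolute incremental
  costs and effects are not comparable to real-population estimates.
- Treatment access, the occlusal-molar share and the other-healthcare item
  fees are assumption-driven defaults; sensitivity to them should be
  explored through the config surface before any substantive use.
- QALYs from child utility instruments are known to be insensitive to
  caries; the QALY stream inherits that limitation by construction.
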