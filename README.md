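# cariescea

Closed-cohort Markov modelling and probabilistic cost-effectiveness analysis
of dental-caries preventive interventions for Australian children from
low-household-income families.

The package is aimed at health economists and oral-health researchers who
want a transparent, scriptable re-implementation of a population-level
priority-setting analysis: five preventive interventions are compared
against a no-intervention comparator on incremental cost, decayed teeth
(DT) prevented, DALYs averted and QALYs gained, with probabilistic
sensitivity analysis (PSA), incremental cost-effectiveness ratios (ICERs)
and cost-effectiveness probabilities at willingness-to-pay thresholds of
AUD$50,000 per DALY averted and AUD$28,033 per QALY gained (2020 AUD
throughout).

## The model

A fixed cohort moves through four health states — caries-free, caries,
edentulous, dead — in one-year cycles over a 2-, 6- or 12-year horizon:

- incidence: a caries-free child develops a new case in a cycle with
  an age-specific per-person probability, split between deciduous and
  permanent dentition by a mixed-dentition eruption profile (all-deciduous
  below age 6, all-permanent from age 14);
- a case is valued as a 28-day symptomatic episode: with probability
  *s* (toothache fraction, mid-range 0.147) the child accrues
  `dw x s x 28/365` DALYs (disability weight *dw* = 0.010) and forgoes
  `u x s x 28/365` QALYs (utility gain *u* = 0.05, half the decrement from
  the 0.9 caries utility), plus treatment costs (check-up AUD$54.69 and
  AUD$189.61 per decayed tooth, 1.64 teeth per case, reached by the
  fraction of cases with treatment access);
- death follows age/sex background mortality and is absorbing; edentulism
  is structurally present but has zero inflow at child ages;
- costs and outcomes are discounted at 3% per year.

The five interventions: anticipatory guidance by oral health therapists via
home visits (**1a**, cumulative dmft change −0.15 over 6 years) or
telehealth (**1b**, −0.18); school-based six-monthly fluoride varnish by
dental practitioners (**2a**) or non-dental professionals at a 76.9%
step-down fee (**2b**), both with preventive fractions 0.37 (deciduous) and
0.43 (permanent) over 2 years; and a school-based fissure-sealant program
(**3**, odds ratio 0.12 applied only to the occlusal-molar share of
permanent incidence). The PSA draws effect sizes, valuation parameters and
fee items from truncated normal distributions and reports ratio-of-means
ICERs and the share of iterations with positive net monetary benefit
`WTP x Δeffect − Δcost`.

National incidence extracts and per-age census counts are not
redistributable, so a synthetic-epidemiology module generates seeded
incidence and mortality schedules with the structure the model assumes
(smooth age profile, 1.5x low-income adjustment, U-shaped child mortality
with a male excess); schedules round-trip through tidy CSV so real extracts
can be substituted.

## Worked example

```sh
cariescea run --interventions 2b,3 --seed 1 --n-iter 200 --out-dir demo
```

writes `report.csv`, a human-readable `report_summary.txt` and a
`manifest.json`, printing (abridged):

```
intervention  delta_dt_mean  delta_daly_mean  delta_qaly_mean  icer_per_dt  icer_per_qaly  ce_prob_qaly
          2b   74065.154378         4.535106        32.383591   480.622210   1.099241e+06           0.0
           3    4974.356288         0.304516         2.154519  4235.735008   9.779470e+06           0.0
```

Read: over its 2-year horizon the non-dental-professional varnish program
(2b) prevents ~74,000 decayed teeth in the 333,651-child cohort at
AUD$481 per tooth prevented, but its cost per QALY gained (~AUD$1.1M)
dwarfs the AUD$28,033 threshold, so its cost-effectiveness probability is
0 — the sealant program (3) even more so. The same interface runs the
widened-healthcare-cost scenario (`--scenario other_healthcare_costs`) and
the 12-year extrapolation (`--scenario extrapolation_12y`), in which
effects persist with 0% decay while program costs stay within their
original windows.

Library use mirrors the CLI:

```python
from cariescea import builtin_config, builtin_intervention, run_psa, summarize

cfg = builtin_config("2b")
res = run_psa(cfg, builtin_intervention("2b"), n_iter=2000, seed=1)
print(summarize({"2b": res}))
```

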