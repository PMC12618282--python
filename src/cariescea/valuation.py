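"""Per-case valuation: decayed teeth, DALYs, QALYs and healthcare costs.

A caries case is valued as a 28-day symptomatic episode, not a year lived in
the caries state: the disability weight (or the averted utility gain) applies
only to the symptomatic fraction of cases and only for the episode duration.
There is no years-of-life-lost term — caries is non-fatal in the model and
death arises solely from background mortality.  Edentulism carries no value
at the modelled ages.

Each function accepts optional overrides for the parameters the PSA samples,
so the deterministic run and a Monte Carlo iteration share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import CostParams, EpisodeValuation

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class EpisodeOutcome:
    """Composite per-case quantities for one parameter set."""

    dt_per_case: float
    yld_per_case: float
    qaly_gain_per_case: float
    treatment_cost_per_case: float
    hospitalisation_cost_per_case: float

    def __post_init__(self) -> None:
        for name in ("dt_per_case", "yld_per_case", "qaly_gain_per_case",
                     "treatment_cost_per_case", "hospitalisation_cost_per_case"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def yld_per_case(valuation: EpisodeValuation,
                 disability_weight: float | None = None,
                 symptomatic_fraction: float | None = None) -> float:
    """Years lived with disability per incident case.

    dw x symptomatic fraction x episode duration / 365; with the reference
    parameters 0.010 x 0.147 x 28/365 ~ 1.13e-4 DALY per case.
    """
    dw = valuation.disability_weight if disability_weight is None else disability_weight
    sf = valuation.symptomatic_fraction_value if symptomatic_fraction is None else symptomatic_fraction
    return dw * sf * valuation.episode_duration_days / DAYS_PER_YEAR


def qaly_gain_per_case(valuation: EpisodeValuation,
                       utility_gain: float | None = None,
                       symptomatic_fraction: float | None = None) -> float:
    """QALYs gained by preventing one case (same episode construction)."""
    ug = valuation.utility_gain if utility_gain is None else utility_gain
    sf = valuation.symptomatic_fraction_value if symptomatic_fraction is None else symptomatic_fraction
    return ug * sf * valuation.episode_duration_days / DAYS_PER_YEAR


def cases_to_decayed_teeth(cases: float, valuation: EpisodeValuation,
                           teeth_per_case: float | None = None) -> float:
    if cases < 0:
        raise ValueError("cases must be >= 0")
    tpc = valuation.teeth_per_case if teeth_per_case is None else teeth_per_case
    return cases * tpc


def treatment_cost_per_case(costs: CostParams, valuation: EpisodeValuation,
                            teeth_per_case: float | None = None) -> float:
    """Expected check-up + restoration cost per incident case.

    Only the fraction ``treatment_access_prob`` of cases reaches care, so the
    fee total (check-up plus one restoration per decayed tooth) is scaled by
    the access probability.
    """
    tpc = valuation.teeth_per_case if teeth_per_case is None else teeth_per_case
    return costs.treatment_access_prob * (
        costs.checkup_fee + tpc * costs.restoration_fee_per_tooth)


def other_healthcare_cost_per_case(costs: CostParams, age: float,
                                   toothache: bool, scenario: str,
                                   hospitalisation_eligible: bool = True) -> float:
    """Extra per-case healthcare cost under the widened-cost scenarios.

    Returns 0 in the base case.  Otherwise: a public/private
    sector-weighted yearly fee for additional caries-related items, plus the
    hospitalisation and dental general-anaesthesia costs — the latter only
    for children aged < 7 who are experiencing toothache, and only in models
    where hospitalisation data apply (``hospitalisation_eligible``).
    """
    if scenario not in ("other_healthcare_costs", "extrapolation_12y"):
        return 0.0
    cost = (costs.public_sector_weight * costs.other_items_public
            + costs.private_sector_weight * costs.other_items_private)
    if hospitalisation_eligible and toothache and age < 7.0:
        cost += costs.hospitalisation_cost + costs.ga_cost
    return cost


def expected_other_healthcare_cost_per_case(costs: CostParams,
                                            valuation: EpisodeValuation,
                                            age: float, scenario: str,
                                            hospitalisation_eligible: bool = True,
                                            symptomatic_fraction: float | None = None) -> float:
    """Toothache-probability-weighted expectation of the scenario cost."""
    sf = valuation.symptomatic_fraction_value if symptomatic_fraction is None else symptomatic_fraction
    with_ta = other_healthcare_cost_per_case(costs, age, True, scenario,
                                             hospitalisation_eligible)
    without = other_healthcare_cost_per_case(costs, age, False, scenario,
                                             hospitalisation_eligible)
    return sf * with_ta + (1.0 - sf) * without


def episode_outcome(costs: CostParams, valuation: EpisodeValuation,
                    age: float, scenario: str = "base_case",
                    hospitalisation_eligible: bool = True) -> EpisodeOutcome:
    """Bundle all per-case quantities for one age and scenario."""
    return EpisodeOutcome(
        dt_per_case=valuation.teeth_per_case,
        yld_per_case=yld_per_case(valuation),
        qaly_gain_per_case=qaly_gain_per_case(valuation),
        treatment_cost_per_case=treatment_cost_per_case(costs, valuation),
        hospitalisation_cost_per_case=expected_other_healthcare_cost_per_case(
            costs, valuation, age, scenario, hospitalisation_eligible),
    )
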