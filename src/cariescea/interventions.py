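"""The five preventive interventions: effect transforms and cost streams.

Three effect mechanisms are modelled, each isolated in one function so the
conversion from trial evidence to transition-rate adjustment can be swapped:

* ``ABS_DMFT_REDUCTION`` — anticipatory guidance (1a home visits, 1b
  telehealth): a cumulative mean dmft difference over the 6-year window is
  converted to a flat per-cycle case-probability reduction on deciduous
  incidence via teeth-per-case.
* ``PREVENTIVE_FRACTION`` — fluoride varnish (2a dental practitioners, 2b
  non-dental professionals): rate x (1 - PF), with separate PFs for
  deciduous (0.37) and permanent (0.43) dentition.  2a and 2b share the
  effect stream and differ only in cost.
* ``ODDS_RATIO`` — fissure sealants (3): an odds ratio of 0.12 applied only
  to the occlusal-molar share of permanent incidence.

Cost streams follow the published visit schedules; dental screening (a
cost-only component with no modelled effect) is added to the first visit of
2a and 3, and the non-dental-professional arm 2b applies a step-down
reimbursement factor to the varnish fee.  Travel costs for the school-based
programs are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

from .parameters import CohortSpec, ConfigError, CostParams

log = logging.getLogger(__name__)
_clip_warned: set[str] = set()


class EffectKind(str, Enum):
    ABS_DMFT_REDUCTION = "abs_dmft_reduction"
    PREVENTIVE_FRACTION = "preventive_fraction"
    ODDS_RATIO = "odds_ratio"


@dataclass(frozen=True)
class InterventionSpec:
    """One intervention: effect transform, effect window, visits and fees.

    ``visits_per_year`` has one entry per year of the cost window; the fee
    for a visit is the sum of the named :class:`CostParams` attributes in
    ``fee_components_per_visit`` times ``fee_units_per_visit``, with the
    step-down reimbursement factor applied when ``apply_stepdown`` is set.
    Effectiveness applies at 100% for every cycle of the effect window
    (``decay_rate`` 0 by default).
    """

    id: str
    label: str
    effect_kind: EffectKind
    effect_window_years: int
    target_dentition: str  # "deciduous" | "both" | "permanent_occlusal"
    visits_per_year: tuple[int, ...]
    fee_components_per_visit: tuple[str, ...]
    fee_units_per_visit: float = 1.0
    apply_stepdown: bool = False
    includes_screening_first_visit: bool = False
    provider: str = "dental_practitioner"
    decay_rate: float = 0.0
    delta_dmft: float | None = None
    delta_dmft_sd: float = 0.0
    pf_deciduous: float | None = None
    pf_deciduous_sd: float = 0.0
    pf_permanent: float | None = None
    pf_permanent_sd: float = 0.0
    odds_ratio: float | None = None
    odds_ratio_sd: float = 0.0
    reported_first_year_cost_millions: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.decay_rate <= 1.0:
            raise ConfigError(f"intervention {self.id}: decay_rate must be in [0, 1]")
        if self.effect_kind is EffectKind.PREVENTIVE_FRACTION:
            for name in ("pf_deciduous", "pf_permanent"):
                v = getattr(self, name)
                if v is None or not 0.0 <= v <= 1.0:
                    raise ConfigError(f"intervention {self.id}: {name} must be in [0, 1]")
        if self.effect_kind is EffectKind.ODDS_RATIO:
            if self.odds_ratio is None or self.odds_ratio <= 0:
                raise ConfigError(f"intervention {self.id}: odds_ratio must be > 0")
        if self.effect_kind is EffectKind.ABS_DMFT_REDUCTION:
            if self.delta_dmft is None or self.delta_dmft > 0:
                raise ConfigError(f"intervention {self.id}: delta_dmft must be <= 0")
        if self.includes_screening_first_visit and self.id not in ("2a", "3"):
            raise ConfigError(
                f"intervention {self.id}: screening applies only to 2a and 3")

    @property
    def cost_window_years(self) -> int:
        return len(self.visits_per_year)


# ---------------------------------------------------------------------------
# Effect transforms
# ---------------------------------------------------------------------------

def apply_preventive_fraction(rate: float, pf: float) -> float:
    """Adjusted rate = rate x (1 - PF)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if not 0.0 <= pf <= 1.0:
        raise ValueError("preventive fraction must be in [0, 1]")
    return rate * (1.0 - pf)


def odds_ratio_to_adjusted_risk(p0: float, or_value: float) -> float:
    """Convert a baseline risk through an odds ratio: or*p0/(1-p0+or*p0)."""
    if not 0.0 <= p0 < 1.0:
        raise ValueError("baseline risk must be in [0, 1); p0 = 1 is degenerate")
    if or_value <= 0:
        raise ValueError("odds ratio must be > 0")
    return or_value * p0 / (1.0 - p0 + or_value * p0)


def anticipatory_guidance_case_reduction(delta_dmft: float, teeth_per_case: float,
                                         window_years: int) -> float:
    """Per-cycle case-probability reduction from a cumulative dmft change.

    |delta_dmft| teeth averted per child over the window, at
    ``teeth_per_case`` decayed teeth per case, spread uniformly:
    |delta_dmft| / teeth_per_case / window_years cases/person/cycle.
    """
    if delta_dmft > 0:
        raise ValueError("delta_dmft must be <= 0 (a reduction)")
    if window_years <= 0:
        raise ValueError("window_years must be > 0")
    if teeth_per_case <= 0:
        raise ValueError("teeth_per_case must be > 0")
    return -delta_dmft / teeth_per_case / window_years


def adjusted_incidence(spec: InterventionSpec, dec_rate: float, perm_rate: float,
                       *, occlusal_molar_share: float, teeth_per_case: float,
                       effect: Mapping[str, float] | None = None) -> tuple[float, float]:
    """Apply an intervention's effect to per-dentition incidence rates.

    ``effect`` optionally overrides the spec's mean effect values with a PSA
    draw (keys ``delta_dmft`` / ``pf_deciduous`` / ``pf_permanent`` /
    ``odds_ratio``).  Returns the adjusted (deciduous, permanent) rates.
    """
    e = dict(effect or {})
    if spec.effect_kind is EffectKind.ABS_DMFT_REDUCTION:
        reduction = anticipatory_guidance_case_reduction(
            e.get("delta_dmft", spec.delta_dmft), teeth_per_case,
            spec.effect_window_years)
        if reduction > dec_rate:
            # warn once per intervention per process; repeats at DEBUG
            level = logging.DEBUG if spec.id in _clip_warned else logging.WARNING
            _clip_warned.add(spec.id)
            log.log(level,
                    "intervention %s: case reduction %.4g exceeds deciduous "
                    "incidence %.4g; clipping to zero incidence",
                    spec.id, reduction, dec_rate)
        return max(0.0, dec_rate - reduction), perm_rate
    if spec.effect_kind is EffectKind.PREVENTIVE_FRACTION:
        pf_d = min(1.0, max(0.0, e.get("pf_deciduous", spec.pf_deciduous)))
        pf_p = min(1.0, max(0.0, e.get("pf_permanent", spec.pf_permanent)))
        return apply_preventive_fraction(dec_rate, pf_d), apply_preventive_fraction(perm_rate, pf_p)
    # odds ratio on the occlusal-molar share of permanent incidence only
    or_value = e.get("odds_ratio", spec.odds_ratio)
    occlusal = perm_rate * occlusal_molar_share
    rest = perm_rate - occlusal
    return dec_rate, rest + odds_ratio_to_adjusted_risk(occlusal, or_value)


# ---------------------------------------------------------------------------
# Cost streams
# ---------------------------------------------------------------------------

def per_child_cost_for_year(spec: InterventionSpec, costs: CostParams,
                            year_index: int) -> float:
    """Intervention cost per enrolled child in ``year_index`` (0-based).

    Zero after the cost window.  The first year adds the screening fee when
    flagged; the step-down reimbursement factor scales the per-visit fee for
    the non-dental-professional arm.
    """
    if year_index < 0:
        raise ValueError("year_index must be >= 0")
    if year_index >= spec.cost_window_years:
        return 0.0
    fee = sum(getattr(costs, name) for name in spec.fee_components_per_visit)
    fee *= spec.fee_units_per_visit
    if spec.apply_stepdown:
        fee *= costs.stepdown_factor
    total = spec.visits_per_year[year_index] * fee
    if year_index == 0 and spec.includes_screening_first_visit:
        total += costs.screening_fee
    return total


def intervention_cost_for_year(spec: InterventionSpec, costs: CostParams,
                               cohort: CohortSpec, year_index: int) -> float:
    """Program-level cost (AUD) for the whole enrolled cohort in one year."""
    return cohort.size_low_income * per_child_cost_for_year(spec, costs, year_index)


def total_undiscounted_cost(spec: InterventionSpec, costs: CostParams,
                            cohort: CohortSpec) -> float:
    return sum(intervention_cost_for_year(spec, costs, cohort, y)
               for y in range(spec.cost_window_years))


# ---------------------------------------------------------------------------
# Built-in specs
# ---------------------------------------------------------------------------

_BUILTIN: dict[str, InterventionSpec] = {
    # 11 home visits over 6 years: 1 in year 0 then 2/year, each visit a
    # consultation plus travel.
    "1a": InterventionSpec(
        id="1a", label="Anticipatory guidance (home visits)",
        effect_kind=EffectKind.ABS_DMFT_REDUCTION, effect_window_years=6,
        target_dentition="deciduous",
        visits_per_year=(1, 2, 2, 2, 2, 2),
        fee_components_per_visit=("home_visit_consult", "home_visit_travel"),
        provider="oral_health_therapist",
        delta_dmft=-0.15, delta_dmft_sd=0.0375,
    ),
    "1b": InterventionSpec(
        id="1b", label="Anticipatory guidance (telehealth)",
        effect_kind=EffectKind.ABS_DMFT_REDUCTION, effect_window_years=6,
        target_dentition="deciduous",
        visits_per_year=(1, 2, 2, 2, 2, 2),
        fee_components_per_visit=("telehealth_consult",),
        provider="oral_health_therapist",
        delta_dmft=-0.18, delta_dmft_sd=0.045,
    ),
    "2a": InterventionSpec(
        id="2a", label="School fluoride varnish (dental practitioners)",
        effect_kind=EffectKind.PREVENTIVE_FRACTION, effect_window_years=2,
        target_dentition="both",
        visits_per_year=(2, 2),
        fee_components_per_visit=("varnish_fee",),
        includes_screening_first_visit=True,
        provider="dental_practitioner",
        pf_deciduous=0.37, pf_deciduous_sd=0.07,
        pf_permanent=0.43, pf_permanent_sd=0.07,
        reported_first_year_cost_millions=34.6,  # published figure; fee arithmetic gives 34.3
    ),
    "2b": InterventionSpec(
        id="2b", label="School fluoride varnish (non-dental professionals)",
        effect_kind=EffectKind.PREVENTIVE_FRACTION, effect_window_years=2,
        target_dentition="both",
        visits_per_year=(2, 2),
        fee_components_per_visit=("varnish_fee",),
        apply_stepdown=True,
        provider="non_dental_professional",
        pf_deciduous=0.37, pf_deciduous_sd=0.07,
        pf_permanent=0.43, pf_permanent_sd=0.07,
    ),
    # Four sealants (all four first or second permanent molars) in one
    # first-year visit, plus screening; no further program cost.
    "3": InterventionSpec(
        id="3", label="School fissure sealants",
        effect_kind=EffectKind.ODDS_RATIO, effect_window_years=2,
        target_dentition="permanent_occlusal",
        visits_per_year=(1,),
        fee_components_per_visit=("sealant_fee_per_tooth",),
        fee_units_per_visit=4.0,
        includes_screening_first_visit=True,
        provider="dental_practitioner",
        odds_ratio=0.12, odds_ratio_sd=0.03,
    ),
}


def builtin_intervention(intervention_id: str) -> InterventionSpec:
    """Reference :class:`InterventionSpec` for one of the five interventions."""
    try:
        return _BUILTIN[intervention_id]
    except KeyError:
        raise ConfigError(
            f"unknown intervention id {intervention_id!r}; "
            f"expected one of {tuple(_BUILTIN)}") from None
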