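"""Closed-cohort four-state Markov engine with one-year cycles.

States are caries-free, caries, edentulous and dead.  The cohort is
propagated as deterministic expected-value occupancy (fractional persons);
parameter uncertainty is handled by the PSA layer, not by microsimulation.
Death is absorbing; edentulism has zero inflow at the modelled ages (the
state is retained for structural fidelity only).  An incident case occupies
the caries state for one cycle and then returns to caries-free under the
default recovery policy ("one_cycle"); an "absorbing" policy keeping cases
in the caries state is selectable.

Accounting follows event semantics: incident cases (and the teeth, episode
DALYs/QALYs and per-case costs they carry) are counted when they occur,
while occupancy-derived quantities (alive person-years) use half-cycle
(trapezoid) within-cycle correction by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from enum import IntEnum

import numpy as np
import pandas as pd

from .interventions import InterventionSpec, adjusted_incidence, per_child_cost_for_year
from .parameters import ModelConfig
from .synthetic_epi import split_mixed_dentition
from .valuation import (
    expected_other_healthcare_cost_per_case,
    qaly_gain_per_case,
    treatment_cost_per_case,
    yld_per_case,
)


class HealthState(IntEnum):
    CARIES_FREE = 0
    CARIES = 1
    EDENTULOUS = 2
    DEAD = 3


N_STATES = len(HealthState)


class EngineError(RuntimeError):
    """Internal consistency violation (negative occupancy, mass loss)."""


def discount(amount: float, cycle_index: int, rate: float) -> float:
    """Present value of ``amount`` accruing in cycle ``cycle_index``.

    Cycle 0 is undiscounted; thereafter amount / (1 + rate)**cycle_index.
    """
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    return amount / (1.0 + rate) ** cycle_index


def transition_step(occupancy: np.ndarray, age: float, dec_rate: float,
                    perm_rate: float, mortality: float,
                    recovery_rule: str = "one_cycle") -> np.ndarray:
    """One-cycle transition of the occupancy vector at ``age``.

    Mortality applies uniformly to the alive states; survivors of the
    caries-free state develop a new case with probability
    ``dec_rate + perm_rate``.  Mass is conserved exactly and the dead state
    never decreases.  Edentulous has no inflow at the modelled (child) ages.
    """
    occ = np.asarray(occupancy, dtype=float)
    if occ.shape != (N_STATES,):
        raise EngineError(f"occupancy must have {N_STATES} states")
    if np.any(occ < -1e-9):
        raise EngineError(f"negative occupancy: {occ}")
    p_case = min(dec_rate + perm_rate, 1.0)
    if p_case < 0:
        raise EngineError("negative incidence after adjustment")
    m = mortality
    cf, ca, ed, de = occ
    surv_cf = cf * (1.0 - m)
    new_cases = surv_cf * p_case
    surv_ca = ca * (1.0 - m)
    if recovery_rule == "one_cycle":
        new_cf = surv_cf - new_cases + surv_ca
        new_ca = new_cases
    elif recovery_rule == "absorbing":
        new_cf = surv_cf - new_cases
        new_ca = new_cases + surv_ca
    else:
        raise ValueError(f"unknown recovery_rule {recovery_rule!r}")
    new_ed = ed * (1.0 - m)
    new_de = de + m * (cf + ca + ed)
    return np.array([new_cf, new_ca, new_ed, new_de])


@dataclass
class CycleTrace:
    """Per-cycle occupancy and accumulators for one arm of one scenario.

    ``occupancy[t]`` is the start of cycle ``t`` (so the array has one extra
    row for the end of the horizon).  All accumulator arrays are
    undiscounted; the ``*_disc`` properties apply the stored per-cycle
    discount factors.
    """

    horizon: int
    discount_rate: float
    occupancy: np.ndarray          # (horizon + 1, 4) persons
    person_years: np.ndarray       # (horizon,) alive person-years (WCC applied)
    cases_deciduous: np.ndarray    # (horizon,) incident cases
    cases_permanent: np.ndarray
    decayed_teeth: np.ndarray
    cost_intervention: np.ndarray  # AUD
    cost_healthcare: np.ndarray
    dalys: np.ndarray
    qalys: np.ndarray

    @classmethod
    def zeros(cls, horizon: int, discount_rate: float) -> "CycleTrace":
        z = lambda: np.zeros(horizon)
        return cls(horizon, discount_rate, np.zeros((horizon + 1, N_STATES)),
                   z(), z(), z(), z(), z(), z(), z(), z())

    @property
    def discount_factors(self) -> np.ndarray:
        return 1.0 / (1.0 + self.discount_rate) ** np.arange(self.horizon)

    @property
    def cases(self) -> np.ndarray:
        return self.cases_deciduous + self.cases_permanent

    @property
    def cost_total(self) -> np.ndarray:
        return self.cost_intervention + self.cost_healthcare

    def _disc(self, values: np.ndarray) -> np.ndarray:
        return values * self.discount_factors

    @property
    def cases_disc(self) -> np.ndarray:
        return self._disc(self.cases)

    @property
    def decayed_teeth_disc(self) -> np.ndarray:
        return self._disc(self.decayed_teeth)

    @property
    def cost_intervention_disc(self) -> np.ndarray:
        return self._disc(self.cost_intervention)

    @property
    def cost_healthcare_disc(self) -> np.ndarray:
        return self._disc(self.cost_healthcare)

    @property
    def cost_total_disc(self) -> np.ndarray:
        return self._disc(self.cost_total)

    @property
    def dalys_disc(self) -> np.ndarray:
        return self._disc(self.dalys)

    @property
    def qalys_disc(self) -> np.ndarray:
        return self._disc(self.qalys)

    def __add__(self, other: "CycleTrace") -> "CycleTrace":
        if (self.horizon != other.horizon
                or self.discount_rate != other.discount_rate):
            raise ValueError("can only add traces with equal horizon and discount rate")
        return CycleTrace(
            self.horizon, self.discount_rate,
            self.occupancy + other.occupancy,
            self.person_years + other.person_years,
            self.cases_deciduous + other.cases_deciduous,
            self.cases_permanent + other.cases_permanent,
            self.decayed_teeth + other.decayed_teeth,
            self.cost_intervention + other.cost_intervention,
            self.cost_healthcare + other.cost_healthcare,
            self.dalys + other.dalys,
            self.qalys + other.qalys,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle table (occupancy at cycle start plus accumulators)."""
        df = pd.DataFrame({"cycle": np.arange(self.horizon)})
        for state in HealthState:
            df[state.name.lower()] = self.occupancy[:-1, state]
        for name in ("person_years", "cases_deciduous", "cases_permanent",
                     "decayed_teeth", "cost_intervention", "cost_healthcare",
                     "dalys", "qalys"):
            df[name] = getattr(self, name)
            df[name + "_disc"] = self._disc(getattr(self, name))
        return df


def _resolved_params(config: ModelConfig, draw):
    """Pull draw overrides (or config means) for the valued parameters."""
    v, c = config.valuation, config.costs
    if draw is None:
        return v.disability_weight, v.utility_gain, v.symptomatic_fraction_value, \
            v.teeth_per_case, c
    costs = dc_replace(
        c,
        checkup_fee=getattr(draw, "checkup_fee", c.checkup_fee),
        restoration_fee_per_tooth=getattr(draw, "restoration_fee_per_tooth",
                                          c.restoration_fee_per_tooth),
        home_visit_travel=getattr(draw, "home_visit_travel", c.home_visit_travel),
    )
    return (getattr(draw, "disability_weight", v.disability_weight),
            getattr(draw, "utility_gain", v.utility_gain),
            getattr(draw, "symptomatic_fraction", v.symptomatic_fraction_value),
            getattr(draw, "teeth_per_case", v.teeth_per_case),
            costs)


def run_cohort(config: ModelConfig, intervention: InterventionSpec | None = None,
               draw=None) -> CycleTrace:
    """Run one arm (comparator when ``intervention`` is None) of a scenario.

    ``draw`` is an optional PSA parameter draw (see
    :class:`cariescea.psa_cea.ParameterDraw`); without it the parameter
    means are used.  Multi-age cohorts are run per start age and summed.
    The intervention effect applies for its effect window in the base case
    and for every cycle under the 12-year extrapolation, while its cost
    schedule never extends beyond the published cost window.
    """
    H = config.horizon_years
    rate = config.econ.discount_rate_per_year
    dw, ug, sf, tpc, costs = _resolved_params(config, draw)
    effect = None
    if intervention is not None and draw is not None:
        effect = getattr(draw, "effects", {}).get(intervention.id)
    if intervention is not None and intervention.effect_window_years > H:
        raise ValueError(
            f"intervention {intervention.id} effect window "
            f"{intervention.effect_window_years} exceeds horizon {H}")
    yld = yld_per_case(config.valuation, disability_weight=dw, symptomatic_fraction=sf)
    qal = qaly_gain_per_case(config.valuation, utility_gain=ug, symptomatic_fraction=sf)
    treat = treatment_cost_per_case(costs, config.valuation, teeth_per_case=tpc)
    half_cycle = config.within_cycle_correction == "half_cycle"

    trace = CycleTrace.zeros(H, rate)
    for start_age, size in config.cohort.subcohorts():
        occ = np.zeros(N_STATES)
        occ[HealthState.CARIES_FREE] = size
        for t in range(H):
            age = start_age + t
            dec, perm = split_mixed_dentition(config.incidence, age)
            effect_active = intervention is not None and (
                config.scenario == "extrapolation_12y"
                or t < intervention.effect_window_years)
            if effect_active:
                dec, perm = adjusted_incidence(
                    intervention, dec, perm,
                    occlusal_molar_share=config.incidence.occlusal_molar_share,
                    teeth_per_case=tpc, effect=effect)
            m = config.mortality.rate_at(age)
            new_occ = transition_step(occ, age, dec, perm, m,
                                      recovery_rule=config.caries_recovery)
            if abs(new_occ.sum() - occ.sum()) > 1e-6 * max(occ.sum(), 1.0):
                raise EngineError("mass not conserved in transition step")
            surv_cf = occ[HealthState.CARIES_FREE] * (1.0 - m)
            cases_dec = surv_cf * dec
            cases_perm = surv_cf * perm
            cases = cases_dec + cases_perm
            other = expected_other_healthcare_cost_per_case(
                costs, config.valuation, age, config.scenario,
                hospitalisation_eligible=config.include_hospitalisation_costs,
                symptomatic_fraction=sf)
            alive_start = occ[: HealthState.DEAD].sum()
            alive_end = new_occ[: HealthState.DEAD].sum()
            trace.occupancy[t] += occ
            trace.person_years[t] += (0.5 * (alive_start + alive_end)
                                      if half_cycle else alive_start)
            trace.cases_deciduous[t] += cases_dec
            trace.cases_permanent[t] += cases_perm
            trace.decayed_teeth[t] += cases * tpc
            trace.cost_healthcare[t] += cases * (treat + other)
            trace.dalys[t] += cases * yld
            trace.qalys[t] += cases * qal
            if intervention is not None:
                trace.cost_intervention[t] += size * per_child_cost_for_year(
                    intervention, costs, t)
            occ = new_occ
        trace.occupancy[H] += occ
    return trace
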