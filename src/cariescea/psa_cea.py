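"""Probabilistic sensitivity analysis, ICERs and cost-effectiveness probabilities.

Each Monte Carlo iteration samples one :class:`ParameterDraw` (normal
distributions, truncated by resampling to respect sign/range constraints)
and runs the comparator and intervention arms on that same draw (common
random numbers), yielding incremental discounted cost, decayed teeth,
DALYs averted and QALYs gained versus no intervention.

Summaries follow standard cost-effectiveness practice: ICERs are ratios of
means (with explicit dominant / dominated / undefined markers), and the
cost-effectiveness probability at a willingness-to-pay threshold is the
share of iterations with positive net monetary benefit
``wtp x delta_effect - delta_cost``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .interventions import EffectKind, InterventionSpec, builtin_intervention
from .markov_engine import run_cohort
from .parameters import INTERVENTION_IDS, EconSettings, ModelConfig

__all__ = [
    "ParameterDraw", "PsaResult", "Icer", "IcerStatus",
    "sample_parameters", "run_psa", "icer", "ce_probability", "summarize",
]


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  low: float = -math.inf, high: float = math.inf,
                  max_tries: int = 1000) -> float:
    """Normal draw truncated to [low, high] by resampling; sd 0 -> mean."""
    if sd == 0.0:
        return min(max(mean, low), high)
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    return min(max(mean, low), high)  # pathological bounds; fall back to mean


@dataclass(frozen=True)
class ParameterDraw:
    """One sampled parameter vector, fully determined by (seed, iteration)."""

    disability_weight: float
    baseline_utility: float
    symptomatic_fraction: float
    teeth_per_case: float
    checkup_fee: float
    restoration_fee_per_tooth: float
    home_visit_travel: float
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    @property
    def utility_gain(self) -> float:
        return (1.0 - self.baseline_utility) / 2.0


def _sample_effect(rng: np.random.Generator, spec: InterventionSpec) -> dict[str, float]:
    if spec.effect_kind is EffectKind.ABS_DMFT_REDUCTION:
        return {"delta_dmft": _trunc_normal(rng, spec.delta_dmft,
                                            spec.delta_dmft_sd, high=0.0)}
    if spec.effect_kind is EffectKind.PREVENTIVE_FRACTION:
        return {
            "pf_deciduous": _trunc_normal(rng, spec.pf_deciduous,
                                          spec.pf_deciduous_sd, 0.0, 1.0),
            "pf_permanent": _trunc_normal(rng, spec.pf_permanent,
                                          spec.pf_permanent_sd, 0.0, 1.0),
        }
    return {"odds_ratio": _trunc_normal(rng, spec.odds_ratio,
                                        spec.odds_ratio_sd, low=1e-9)}


def sample_parameters(config: ModelConfig, seed: int, iteration: int,
                      interventions: Sequence[InterventionSpec] | None = None
                      ) -> ParameterDraw:
    """Reproducible parameter draw for one PSA iteration.

    The draw covers every uncertain parameter: episode valuation (disability
    weight >= 0, baseline utility in [0, 1], teeth per case > 0), the fee
    items with published SDs (>= 0), and each intervention's effect size.
    Degenerate distributions (sd 0) return the mean deterministically.
    """
    if interventions is None:
        interventions = [builtin_intervention(i) for i in INTERVENTION_IDS]
    v, c = config.valuation, config.costs
    rng = np.random.default_rng([int(seed), int(iteration), 7])
    draw = ParameterDraw(
        disability_weight=_trunc_normal(rng, v.disability_weight,
                                        v.disability_weight_sd, low=0.0),
        baseline_utility=_trunc_normal(rng, v.baseline_utility,
                                       v.baseline_utility_sd, 0.0, 1.0),
        # published as a range, not a distribution: held at its resolved value
        symptomatic_fraction=v.symptomatic_fraction_value,
        teeth_per_case=_trunc_normal(rng, v.teeth_per_case,
                                     v.teeth_per_case_sd, low=1e-6),
        checkup_fee=_trunc_normal(rng, c.checkup_fee, c.checkup_fee_sd, low=0.0),
        restoration_fee_per_tooth=_trunc_normal(
            rng, c.restoration_fee_per_tooth, c.restoration_fee_per_tooth_sd, low=0.0),
        home_visit_travel=_trunc_normal(rng, c.home_visit_travel,
                                        c.home_visit_travel_sd, low=0.0),
        effects={s.id: _sample_effect(rng, s)
                 for s in sorted(interventions, key=lambda s: s.id)},
    )
    return draw


@dataclass
class PsaResult:
    """Per-iteration incremental outcomes (intervention minus comparator
    for costs; comparator minus intervention for effects) plus metadata."""

    intervention_id: str
    n_iterations: int
    seed: int
    econ: EconSettings
    delta_cost: np.ndarray
    delta_dt: np.ndarray
    delta_daly: np.ndarray
    delta_qaly: np.ndarray
    delta_cost_undisc: np.ndarray
    delta_dt_undisc: np.ndarray
    delta_daly_undisc: np.ndarray
    delta_qaly_undisc: np.ndarray

    _FIELDS = ("delta_cost", "delta_dt", "delta_daly", "delta_qaly")

    def array(self, name: str, undiscounted: bool = False) -> np.ndarray:
        if name not in self._FIELDS:
            raise KeyError(name)
        return getattr(self, name + ("_undisc" if undiscounted else ""))

    def mean(self, name: str, undiscounted: bool = False) -> float:
        return float(self.array(name, undiscounted).mean())

    def se(self, name: str, undiscounted: bool = False) -> float:
        a = self.array(name, undiscounted)
        if a.size < 2:
            return 0.0
        return float(a.std(ddof=1) / math.sqrt(a.size))

    def icer(self, effect: str, undiscounted: bool = False) -> "Icer":
        """Ratio-of-means ICER for effect in {'dt', 'daly', 'qaly'}."""
        return icer(self.mean("delta_cost", undiscounted),
                    self.mean("delta_" + effect.lower(), undiscounted))

    def to_frame(self, undiscounted: bool = False) -> pd.DataFrame:
        return pd.DataFrame({name: self.array(name, undiscounted)
                             for name in self._FIELDS})


def run_psa(config: ModelConfig, intervention: InterventionSpec, n_iter: int,
            seed: int) -> PsaResult:
    """Monte Carlo PSA of one intervention against the no-intervention arm.

    Each iteration shares a single :class:`ParameterDraw` across both arms,
    so incremental quantities reflect parameter uncertainty only.  The whole
    result is reproducible from ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    out = {f: np.empty(n_iter) for f in
           ("dc", "ddt", "ddaly", "dqaly", "dcu", "ddtu", "ddalyu", "dqalyu")}
    for it in range(n_iter):
        draw = sample_parameters(config, seed, it, interventions=[intervention])
        comp = run_cohort(config, None, draw)
        arm = run_cohort(config, intervention, draw)
        out["dc"][it] = arm.cost_total_disc.sum() - comp.cost_total_disc.sum()
        out["ddt"][it] = comp.decayed_teeth_disc.sum() - arm.decayed_teeth_disc.sum()
        out["ddaly"][it] = comp.dalys_disc.sum() - arm.dalys_disc.sum()
        out["dqaly"][it] = comp.qalys_disc.sum() - arm.qalys_disc.sum()
        out["dcu"][it] = arm.cost_total.sum() - comp.cost_total.sum()
        out["ddtu"][it] = comp.decayed_teeth.sum() - arm.decayed_teeth.sum()
        out["ddalyu"][it] = comp.dalys.sum() - arm.dalys.sum()
        out["dqalyu"][it] = comp.qalys.sum() - arm.qalys.sum()
    return PsaResult(intervention.id, n_iter, seed, config.econ,
                     out["dc"], out["ddt"], out["ddaly"], out["dqaly"],
                     out["dcu"], out["ddtu"], out["ddalyu"], out["dqalyu"])


class IcerStatus(str, Enum):
    VALUE = "value"
    DOMINANT = "dominant"        # cheaper and more effective
    DOMINATED = "dominated"      # costlier and less effective
    UNDEFINED = "undefined"      # zero incremental effect


@dataclass(frozen=True)
class Icer:
    status: IcerStatus
    value: float  # AUD per effect unit; NaN unless status is VALUE

    def sort_key(self) -> float:
        """Ascending cost-effectiveness order; dominant first, undefined last."""
        if self.status is IcerStatus.DOMINANT:
            return -math.inf
        if self.status is IcerStatus.VALUE:
            return self.value
        return math.inf

    def label(self) -> str:
        return self.status.value if self.status is not IcerStatus.VALUE \
            else f"{self.value:,.0f}"


def icer(delta_cost: float, delta_effect: float) -> Icer:
    """Incremental cost-effectiveness ratio with dominance handling."""
    if delta_effect == 0.0:
        return Icer(IcerStatus.UNDEFINED, math.nan)
    if delta_cost < 0.0 and delta_effect > 0.0:
        return Icer(IcerStatus.DOMINANT, math.nan)
    if delta_cost > 0.0 and delta_effect < 0.0:
        return Icer(IcerStatus.DOMINATED, math.nan)
    return Icer(IcerStatus.VALUE, delta_cost / delta_effect)


def ce_probability(result: PsaResult, wtp: float, effect: str = "DALY") -> float:
    """Share of iterations with positive net monetary benefit at ``wtp``."""
    if wtp <= 0:
        raise ValueError("wtp must be > 0")
    eff = result.array("delta_" + effect.lower())
    nmb = wtp * eff - result.delta_cost
    return float(np.mean(nmb > 0.0))


def summarize(results: Mapping[str, PsaResult] | Iterable[PsaResult],
              undiscounted: bool = False) -> pd.DataFrame:
    """League table: one row per intervention, ranked by AUD per DT prevented.

    Columns give mean (SE) incremental cost and effects, the three ICERs
    (AUD/DT, AUD/DALY, AUD/QALY; NaN with a status label when dominant,
    dominated or undefined) and the CE probabilities at the configured WTP
    thresholds.
    """
    if isinstance(results, Mapping):
        results = list(results.values())
    else:
        results = list(results)
    if not results:
        raise ValueError("need at least one PsaResult")
    rows = []
    for r in results:
        row: dict[str, object] = {"intervention": r.intervention_id,
                                  "n_iterations": r.n_iterations}
        for name in PsaResult._FIELDS:
            row[name + "_mean"] = r.mean(name, undiscounted)
            row[name + "_se"] = r.se(name, undiscounted)
        for eff in ("dt", "daly", "qaly"):
            ic = r.icer(eff, undiscounted)
            row[f"icer_per_{eff}"] = ic.value
            row[f"icer_per_{eff}_status"] = ic.status.value
        row["ce_prob_daly"] = ce_probability(r, r.econ.wtp_per_daly, "DALY")
        row["ce_prob_qaly"] = ce_probability(r, r.econ.wtp_per_qaly, "QALY")
        row["_rank_key"] = r.icer("dt", undiscounted).sort_key()
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        ["_rank_key", "delta_cost_mean"]).drop(columns="_rank_key")
    return df.reset_index(drop=True)
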