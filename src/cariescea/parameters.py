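"""Typed parameter containers, validation and config-file I/O.

Every quantity the model consumes lives in one of the dataclasses below so a
scenario is fully described by a single :class:`ModelConfig`.  Monetary values
are 2020 Australian dollars throughout; key names in the on-disk YAML schema
carry explicit units (``discount_rate_per_year``, ``episode_duration_days``)
so a config file can be audited without reading the code.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from .synthetic_epi import (
    IncidenceSchedule,
    MortalitySchedule,
    make_incidence_schedule,
    make_mortality_schedule,
)

SCENARIOS = ("base_case", "other_healthcare_costs", "extrapolation_12y")
RECOVERY_POLICIES = ("one_cycle", "absorbing")
WCC_MODES = ("half_cycle", "none")
VALID_HORIZONS = (2, 6, 12)


class ConfigError(ValueError):
    """A parameter violates an invariant; the message names the field."""


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ConfigError(message)


@dataclass(frozen=True)
class CohortSpec:
    """A closed cohort of children, possibly spread over several start ages.

    ``size_low_income`` is the number of children from low-household-income
    families actually enrolled; ``size_total`` the total population of that
    age band (context only).  When several start ages are given the enrolled
    count is split evenly across them (per-age census counts are not part of
    the inputs).
    """

    label: str
    start_ages_years: tuple[float, ...]
    size_low_income: int
    size_total: int

    def __post_init__(self) -> None:
        _require(len(self.start_ages_years) > 0, "cohort.start_ages_years must be non-empty")
        _require(all(a >= 0 for a in self.start_ages_years),
                 "cohort.start_ages_years must all be >= 0")
        _require(0 <= self.size_low_income <= self.size_total,
                 "cohort.size_low_income must satisfy 0 <= size_low_income <= size_total "
                 f"(got {self.size_low_income} of {self.size_total})")

    def subcohorts(self) -> list[tuple[float, float]]:
        """(start_age, persons) pairs with the enrolled count split evenly."""
        n = len(self.start_ages_years)
        return [(a, self.size_low_income / n) for a in self.start_ages_years]


@dataclass(frozen=True)
class EpisodeValuation:
    """How one incident caries case is valued in DALYs, QALYs and teeth.

    A case is a symptomatic 28-day episode: the disability weight (DALY side)
    or the utility gain from averting the episode (QALY side) applies only to
    the symptomatic fraction of cases and only for the episode duration.  The
    utility gain is derived as half of (1 - baseline utility 0.9) = 0.05,
    the deliberate halving reflecting that a caries-free child is not in
    perfect health.
    """

    disability_weight: float = 0.010
    disability_weight_sd: float = 0.004
    baseline_utility: float = 0.9
    baseline_utility_sd: float = 0.120
    symptomatic_fraction_low: float = 0.084
    symptomatic_fraction_high: float = 0.210
    symptomatic_fraction: float | None = None  # None -> mid-range default
    episode_duration_days: float = 28.0
    teeth_per_case: float = 1.64
    teeth_per_case_sd: float = 1.262

    def __post_init__(self) -> None:
        _require(0.0 <= self.disability_weight <= 1.0,
                 "valuation.disability_weight must be in [0, 1]")
        _require(0.0 <= self.symptomatic_fraction_low <= self.symptomatic_fraction_high <= 1.0,
                 "valuation.symptomatic_fraction bounds must satisfy 0 <= low <= high <= 1")
        if self.symptomatic_fraction is not None:
            _require(0.0 <= self.symptomatic_fraction <= 1.0,
                     "valuation.symptomatic_fraction must be in [0, 1]")
        _require(self.episode_duration_days > 0,
                 "valuation.episode_duration_days must be > 0")
        _require(self.teeth_per_case > 0, "valuation.teeth_per_case must be > 0")

    @property
    def utility_gain(self) -> float:
        """Per-episode utility gain: (1 - baseline utility) halved."""
        return (1.0 - self.baseline_utility) / 2.0

    @property
    def symptomatic_fraction_value(self) -> float:
        """Resolved toothache probability (mid-range when not set explicitly)."""
        if self.symptomatic_fraction is not None:
            return self.symptomatic_fraction
        return 0.5 * (self.symptomatic_fraction_low + self.symptomatic_fraction_high)


@dataclass(frozen=True)
class CostParams:
    """Unit fees (2020 AUD) for intervention delivery and caries treatment."""

    checkup_fee: float = 54.69
    checkup_fee_sd: float = 3.19
    restoration_fee_per_tooth: float = 189.61
    restoration_fee_per_tooth_sd: float = 17.95
    treatment_access_prob: float = 0.10
    screening_fee: float = 29.25
    varnish_fee: float = 36.80
    stepdown_factor: float = 0.769
    sealant_fee_per_tooth: float = 49.00
    home_visit_consult: float = 23.33
    home_visit_travel: float = 12.34
    home_visit_travel_sd: float = 0.92
    telehealth_consult: float = 16.04
    public_sector_weight: float = 0.15
    hospitalisation_cost: float = 2700.0
    ga_cost: float = 1050.0
    # Config-driven "other healthcare" yearly fee per case (pulp therapy,
    # extractions, ...), public vs private schedule; illustrative defaults.
    other_items_public: float = 120.0
    other_items_private: float = 180.0

    def __post_init__(self) -> None:
        for name in ("checkup_fee", "restoration_fee_per_tooth", "screening_fee",
                     "varnish_fee", "sealant_fee_per_tooth", "home_visit_consult",
                     "home_visit_travel", "telehealth_consult", "hospitalisation_cost",
                     "ga_cost", "other_items_public", "other_items_private"):
            _require(getattr(self, name) >= 0, f"costs.{name} must be >= 0")
        for name in ("treatment_access_prob", "stepdown_factor", "public_sector_weight"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, f"costs.{name} must be in [0, 1]")

    @property
    def private_sector_weight(self) -> float:
        return 1.0 - self.public_sector_weight


@dataclass(frozen=True)
class EconSettings:
    """Discounting, willingness-to-pay thresholds and PSA controls."""

    discount_rate_per_year: float = 0.03
    wtp_per_daly: float = 50_000.0
    wtp_per_qaly: float = 28_033.0
    reference_year: int = 2020
    n_psa_iterations: int = 2000
    rng_seed: int = 1

    def __post_init__(self) -> None:
        _require(self.discount_rate_per_year >= 0,
                 "econ.discount_rate_per_year must be >= 0")
        _require(self.wtp_per_daly > 0, "econ.wtp_per_daly must be > 0")
        _require(self.wtp_per_qaly > 0, "econ.wtp_per_qaly must be > 0")
        _require(self.n_psa_iterations >= 1, "econ.n_psa_iterations must be >= 1")


@dataclass(frozen=True)
class ModelConfig:
    """Everything one scenario run needs."""

    cohort: CohortSpec
    horizon_years: int
    incidence: IncidenceSchedule
    mortality: MortalitySchedule
    valuation: EpisodeValuation = field(default_factory=EpisodeValuation)
    costs: CostParams = field(default_factory=CostParams)
    econ: EconSettings = field(default_factory=EconSettings)
    scenario: str = "base_case"
    include_hospitalisation_costs: bool = False
    caries_recovery: str = "one_cycle"
    within_cycle_correction: str = "half_cycle"

    def __post_init__(self) -> None:
        _require(self.horizon_years in VALID_HORIZONS,
                 f"horizon_years must be one of {VALID_HORIZONS}, got {self.horizon_years}")
        _require(self.scenario in SCENARIOS,
                 f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        _require(self.caries_recovery in RECOVERY_POLICIES,
                 f"caries_recovery must be one of {RECOVERY_POLICIES}")
        _require(self.within_cycle_correction in WCC_MODES,
                 f"within_cycle_correction must be one of {WCC_MODES}")
        lo = min(self.cohort.start_ages_years)
        hi = max(self.cohort.start_ages_years) + self.horizon_years
        for name, sched in (("incidence", self.incidence), ("mortality", self.mortality)):
            _require(sched.ages.min() <= lo and sched.ages.max() >= hi,
                     f"{name} schedule covers ages [{sched.ages.min():g}, "
                     f"{sched.ages.max():g}] but the cohort needs [{lo:g}, {hi:g}]")


# ---------------------------------------------------------------------------
# Config file I/O (YAML with unit-suffixed keys)
# ---------------------------------------------------------------------------

def config_to_dict(config: ModelConfig) -> dict[str, Any]:
    """Plain-type mapping mirroring the on-disk schema (round-trips exactly)."""
    v, c, e = config.valuation, config.costs, config.econ
    return {
        "cohort": {
            "label": config.cohort.label,
            "start_ages_years": [float(a) for a in config.cohort.start_ages_years],
            "size_low_income_persons": int(config.cohort.size_low_income),
            "size_total_persons": int(config.cohort.size_total),
        },
        "horizon_years": int(config.horizon_years),
        "scenario": config.scenario,
        "include_hospitalisation_costs": bool(config.include_hospitalisation_costs),
        "caries_recovery": config.caries_recovery,
        "within_cycle_correction": config.within_cycle_correction,
        "valuation": {
            "disability_weight": v.disability_weight,
            "disability_weight_sd": v.disability_weight_sd,
            "baseline_utility": v.baseline_utility,
            "baseline_utility_sd": v.baseline_utility_sd,
            "symptomatic_fraction_low": v.symptomatic_fraction_low,
            "symptomatic_fraction_high": v.symptomatic_fraction_high,
            "symptomatic_fraction": v.symptomatic_fraction,
            "episode_duration_days": v.episode_duration_days,
            "teeth_per_case": v.teeth_per_case,
            "teeth_per_case_sd": v.teeth_per_case_sd,
        },
        "costs_aud": {f.name: getattr(c, f.name) for f in dataclasses.fields(c)},
        "econ": {
            "discount_rate_per_year": e.discount_rate_per_year,
            "wtp_per_daly_aud": e.wtp_per_daly,
            "wtp_per_qaly_aud": e.wtp_per_qaly,
            "reference_year": e.reference_year,
            "n_psa_iterations": e.n_psa_iterations,
            "rng_seed": e.rng_seed,
        },
        "incidence": {
            "ages_years": [float(a) for a in config.incidence.ages],
            "general_rate_per_year": [float(r) for r in config.incidence.general],
            "low_income_rate_per_year": [float(r) for r in config.incidence.low_income],
            "low_income_ratio": float(config.incidence.low_income_ratio),
            "deciduous_share": [float(s) for s in config.incidence.deciduous_share],
            "occlusal_molar_share": float(config.incidence.occlusal_molar_share),
        },
        "mortality": {
            "ages_years": [float(a) for a in config.mortality.ages],
            "male_rate_per_year": [float(r) for r in config.mortality.male],
            "female_rate_per_year": [float(r) for r in config.mortality.female],
            "male_fraction": float(config.mortality.male_fraction),
        },
    }


def _get(d: Mapping[str, Any], key: str, where: str) -> Any:
    try:
        return d[key]
    except KeyError:
        raise ConfigError(f"missing field {where}.{key}" if where else f"missing field {key}")


def config_from_dict(data: Mapping[str, Any]) -> ModelConfig:
    co = _get(data, "cohort", "")
    cohort = CohortSpec(
        label=_get(co, "label", "cohort"),
        start_ages_years=tuple(_get(co, "start_ages_years", "cohort")),
        size_low_income=int(_get(co, "size_low_income_persons", "cohort")),
        size_total=int(_get(co, "size_total_persons", "cohort")),
    )
    vd = dict(_get(data, "valuation", ""))
    valuation = EpisodeValuation(**vd)
    cd = dict(_get(data, "costs_aud", ""))
    costs = CostParams(**cd)
    ed = _get(data, "econ", "")
    econ = EconSettings(
        discount_rate_per_year=_get(ed, "discount_rate_per_year", "econ"),
        wtp_per_daly=_get(ed, "wtp_per_daly_aud", "econ"),
        wtp_per_qaly=_get(ed, "wtp_per_qaly_aud", "econ"),
        reference_year=int(ed.get("reference_year", 2020)),
        n_psa_iterations=int(ed.get("n_psa_iterations", 2000)),
        rng_seed=int(ed.get("rng_seed", 1)),
    )
    inc = _get(data, "incidence", "")
    incidence = IncidenceSchedule(
        ages=np.asarray(_get(inc, "ages_years", "incidence"), dtype=float),
        general=np.asarray(_get(inc, "general_rate_per_year", "incidence"), dtype=float),
        low_income=np.asarray(_get(inc, "low_income_rate_per_year", "incidence"), dtype=float),
        low_income_ratio=float(_get(inc, "low_income_ratio", "incidence")),
        deciduous_share=np.asarray(_get(inc, "deciduous_share", "incidence"), dtype=float),
        occlusal_molar_share=float(_get(inc, "occlusal_molar_share", "incidence")),
    )
    mo = _get(data, "mortality", "")
    mortality = MortalitySchedule(
        ages=np.asarray(_get(mo, "ages_years", "mortality"), dtype=float),
        male=np.asarray(_get(mo, "male_rate_per_year", "mortality"), dtype=float),
        female=np.asarray(_get(mo, "female_rate_per_year", "mortality"), dtype=float),
        male_fraction=float(_get(mo, "male_fraction", "mortality")),
    )
    return ModelConfig(
        cohort=cohort,
        horizon_years=int(_get(data, "horizon_years", "")),
        incidence=incidence,
        mortality=mortality,
        valuation=valuation,
        costs=costs,
        econ=econ,
        scenario=data.get("scenario", "base_case"),
        include_hospitalisation_costs=bool(data.get("include_hospitalisation_costs", False)),
        caries_recovery=data.get("caries_recovery", "one_cycle"),
        within_cycle_correction=data.get("within_cycle_correction", "half_cycle"),
    )


def save_config(config: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def load_config(path) -> ModelConfig:
    """Read and fully validate a scenario config file.

    Raises :class:`ConfigError` naming the offending field on any missing
    key, out-of-range value, or schedule/horizon coverage mismatch.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"config file {path} did not parse to a mapping")
    try:
        return config_from_dict(data)
    except TypeError as exc:  # unexpected/missing dataclass kwargs
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Built-in reference parameter set
# ---------------------------------------------------------------------------

_COHORTS: dict[str, CohortSpec] = {
    "1a": CohortSpec("anticipatory guidance, home visits",
                     (0.5,), 45_677, 303_407),
    "1b": CohortSpec("anticipatory guidance, telehealth",
                     (0.5,), 45_677, 303_407),
    "2a": CohortSpec("school fluoride varnish, dental practitioners",
                     tuple(float(a) for a in range(6, 13)), 333_651, 2_236_730),
    "2b": CohortSpec("school fluoride varnish, non-dental professionals",
                     tuple(float(a) for a in range(6, 13)), 333_651, 2_236_730),
    "3": CohortSpec("school fissure sealants, dental practitioners",
                    (6.0, 12.0), 94_025, 638_445),
}

_HORIZONS = {"1a": 6, "1b": 6, "2a": 2, "2b": 2, "3": 2}

INTERVENTION_IDS = tuple(_COHORTS)


def builtin_config(intervention_id: str, scenario: str = "base_case",
                   seed: int = 1) -> ModelConfig:
    """Reference :class:`ModelConfig` for one of the five interventions.

    All fee, valuation and economic parameters are the published Australian
    values; incidence and mortality schedules are generated synthetically
    with the default calibration and the given ``seed``.  ``scenario``
    selects base case, the other-healthcare-costs sensitivity analysis, or
    the 12-year extrapolation (which forces ``horizon_years`` to 12).
    """
    if intervention_id not in _COHORTS:
        raise ConfigError(
            f"unknown intervention id {intervention_id!r}; expected one of {INTERVENTION_IDS}")
    if scenario not in SCENARIOS:
        raise ConfigError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    horizon = 12 if scenario == "extrapolation_12y" else _HORIZONS[intervention_id]
    return ModelConfig(
        cohort=_COHORTS[intervention_id],
        horizon_years=horizon,
        incidence=make_incidence_schedule(seed=seed),
        mortality=make_mortality_schedule(seed=seed),
        scenario=scenario,
        include_hospitalisation_costs=intervention_id in ("1a", "1b"),
    )
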