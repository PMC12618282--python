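"""Synthetic incidence, mortality and dentition inputs.

The model needs three age-indexed inputs that in the original Australian
analysis came from national burden-of-disease extracts and census tables:
per-person annual caries incidence (general population), a multiplicative
low-household-income adjustment, and age/sex background mortality.  This
module generates schedules with the same statistical structure so every
downstream stage is testable without external data.  Schedules round-trip
through tidy CSV (columns: age, group, rate) so real extracts can be
substituted later.

Default calibration: general-population incidence ~0.1-0.2 cases/person/year
declining gently with age, low-income ratio 1.5, and a mixed-dentition split
that moves incident cases from deciduous to permanent teeth linearly between
ages 5 and 14.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IncidenceSchedule",
    "MortalitySchedule",
    "make_incidence_schedule",
    "make_mortality_schedule",
    "split_mixed_dentition",
    "default_deciduous_share",
]

#: male:female mortality hazard ratio used by the generator
MALE_FEMALE_HAZARD_RATIO = 1.35
#: male share of the cohort (shared incidence; mortality differs by sex)
DEFAULT_MALE_FRACTION = 0.512


def default_deciduous_share(ages: np.ndarray) -> np.ndarray:
    """Deciduous share of incident cases: 1 up to age 5, 0 from age 14.

    Linear eruption profile across the mixed-dentition window 5-14 years.
    """
    ages = np.asarray(ages, dtype=float)
    return np.clip((14.0 - ages) / 9.0, 0.0, 1.0)


class ScheduleRangeError(ValueError):
    """An age lookup outside the ages a schedule covers."""


def _interp(ages: np.ndarray, values: np.ndarray, age: float, what: str) -> float:
    if age < ages.min() or age > ages.max():
        raise ScheduleRangeError(
            f"age {age:g} outside {what} schedule range "
            f"[{ages.min():g}, {ages.max():g}]")
    return float(np.interp(age, ages, values))


@dataclass(frozen=True)
class IncidenceSchedule:
    """Age-indexed per-person annual probability of a new caries case.

    ``general`` and ``low_income`` are parallel arrays over ``ages``;
    ``deciduous_share`` gives, per age, the proportion of incident cases
    arising in deciduous teeth (the rest is permanent dentition).
    ``occlusal_molar_share`` is the fraction of *permanent* incidence
    attributable to the occlusal surfaces of the first/second permanent
    molars — the only surfaces a sealant program protects.
    """

    ages: np.ndarray
    general: np.ndarray
    low_income: np.ndarray
    low_income_ratio: float
    deciduous_share: np.ndarray = None  # type: ignore[assignment]
    occlusal_molar_share: float = 0.25

    def __post_init__(self) -> None:
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=float))
        object.__setattr__(self, "general", np.asarray(self.general, dtype=float))
        object.__setattr__(self, "low_income", np.asarray(self.low_income, dtype=float))
        if self.deciduous_share is None:
            object.__setattr__(self, "deciduous_share", default_deciduous_share(self.ages))
        else:
            object.__setattr__(self, "deciduous_share",
                               np.asarray(self.deciduous_share, dtype=float))
        for name in ("general", "low_income", "deciduous_share"):
            v = getattr(self, name)
            if v.shape != self.ages.shape:
                raise ValueError(f"incidence.{name} length must match ages")
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"incidence.{name} must lie in [0, 1]")
        if not 0.0 <= self.occlusal_molar_share <= 1.0:
            raise ValueError("incidence.occlusal_molar_share must be in [0, 1]")

    def rate_at(self, age: float, low_income: bool = True) -> float:
        values = self.low_income if low_income else self.general
        return _interp(self.ages, values, age, "incidence")

    def deciduous_share_at(self, age: float) -> float:
        return _interp(self.ages, self.deciduous_share, age, "incidence")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, values in (("general", self.general), ("low_income", self.low_income)):
            rows.append(pd.DataFrame({
                "age": self.ages, "group": group, "rate": values,
                "deciduous_share": self.deciduous_share,
            }))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, low_income_ratio: float = float("nan"),
                 occlusal_molar_share: float = 0.25) -> "IncidenceSchedule":
        df = pd.read_csv(path)
        gen = df[df["group"] == "general"].sort_values("age")
        low = df[df["group"] == "low_income"].sort_values("age")
        ratio = low_income_ratio
        if np.isnan(ratio):
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = low["rate"].to_numpy() / gen["rate"].to_numpy()
            ratios = ratios[np.isfinite(ratios)]
            ratio = float(np.median(ratios)) if ratios.size else 1.0
        return cls(
            ages=gen["age"].to_numpy(float),
            general=gen["rate"].to_numpy(float),
            low_income=low["rate"].to_numpy(float),
            low_income_ratio=ratio,
            deciduous_share=gen["deciduous_share"].to_numpy(float),
            occlusal_molar_share=occlusal_molar_share,
        )


@dataclass(frozen=True)
class MortalitySchedule:
    """Per-age, per-sex annual death probability and the cohort sex mix."""

    ages: np.ndarray
    male: np.ndarray
    female: np.ndarray
    male_fraction: float = DEFAULT_MALE_FRACTION

    def __post_init__(self) -> None:
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=float))
        object.__setattr__(self, "male", np.asarray(self.male, dtype=float))
        object.__setattr__(self, "female", np.asarray(self.female, dtype=float))
        for name in ("male", "female"):
            v = getattr(self, name)
            if v.shape != self.ages.shape:
                raise ValueError(f"mortality.{name} length must match ages")
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"mortality.{name} must lie in [0, 1]")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("mortality.male_fraction must be in [0, 1]")

    def rate_at(self, age: float, sex: str | None = None) -> float:
        """Annual death probability at ``age`` (sex-mixed unless given)."""
        if sex == "male":
            return _interp(self.ages, self.male, age, "mortality")
        if sex == "female":
            return _interp(self.ages, self.female, age, "mortality")
        mixed = self.male_fraction * self.male + (1.0 - self.male_fraction) * self.female
        return _interp(self.ages, mixed, age, "mortality")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex, values in (("male", self.male), ("female", self.female)):
            rows.append(pd.DataFrame({"age": self.ages, "sex": sex, "rate": values}))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, male_fraction: float = DEFAULT_MALE_FRACTION) -> "MortalitySchedule":
        df = pd.read_csv(path)
        male = df[df["sex"] == "male"].sort_values("age")
        female = df[df["sex"] == "female"].sort_values("age")
        return cls(ages=male["age"].to_numpy(float),
                   male=male["rate"].to_numpy(float),
                   female=female["rate"].to_numpy(float),
                   male_fraction=male_fraction)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _age_curve(ages: np.ndarray) -> np.ndarray:
    # Gentle decline with age: caries onset risk peaks in early childhood
    # around deciduous eruption and tails off through adolescence.
    return np.clip(1.25 - 0.05 * ages, 0.3, None)


def make_incidence_schedule(seed: int = 1,
                            ages: np.ndarray | None = None,
                            base_rate: float = 0.15,
                            low_income_ratio: float = 1.5,
                            noise_sd: float = 0.1,
                            occlusal_molar_share: float = 0.25) -> IncidenceSchedule:
    """Generate a seed-deterministic incidence schedule.

    The age profile is ``base_rate`` x a smooth declining age curve x
    per-age lognormal noise, clipped to [0, 1]; the low-income rate is
    ``min(1, general x low_income_ratio)``.
    """
    if not 0.0 <= base_rate <= 1.0:
        raise ValueError("base_rate must be in [0, 1]")
    if low_income_ratio < 1.0:
        raise ValueError("low_income_ratio must be >= 1")
    if ages is None:
        ages = np.arange(0.0, 26.0)
    ages = np.asarray(ages, dtype=float)
    rng = np.random.default_rng([int(seed), 101])
    noise = np.exp(rng.normal(0.0, noise_sd, size=ages.shape))
    general = np.clip(base_rate * _age_curve(ages) * noise, 0.0, 1.0)
    low_income = np.clip(general * low_income_ratio, 0.0, 1.0)
    if np.all(general == 0.0) or np.all(low_income >= 1.0):
        warnings.warn("degenerate incidence schedule (all-zero or saturated)",
                      stacklevel=2)
    return IncidenceSchedule(ages=ages, general=general, low_income=low_income,
                             low_income_ratio=low_income_ratio,
                             deciduous_share=default_deciduous_share(ages),
                             occlusal_molar_share=occlusal_molar_share)


def _mortality_shape(ages: np.ndarray) -> np.ndarray:
    # U-ish child/adolescent profile: infant peak, mid-childhood dip,
    # mild adolescent rise; >= 1 everywhere so level 1 saturates all ages.
    return 1.0 + 3.0 * np.exp(-ages / 1.2) + 0.04 * np.clip(ages - 10.0, 0.0, None)


def make_mortality_schedule(seed: int = 1,
                            ages: np.ndarray | None = None,
                            level: float = 3e-4,
                            noise_sd: float = 0.05,
                            male_fraction: float = DEFAULT_MALE_FRACTION) -> MortalitySchedule:
    """Generate a seed-deterministic background mortality schedule.

    ``level`` sets the overall annual death probability scale; the female
    rate is ``1 - (1 - level)**(shape x noise)`` (exactly 0 at level 0 and
    exactly 1 at level 1 for every age) and the male rate applies a fixed
    hazard ratio on the survival scale.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError("level must be in [0, 1]")
    if ages is None:
        ages = np.arange(0.0, 26.0)
    ages = np.asarray(ages, dtype=float)
    rng = np.random.default_rng([int(seed), 202])
    shape = _mortality_shape(ages) * np.exp(rng.normal(0.0, noise_sd, size=ages.shape))
    female = 1.0 - np.power(1.0 - level, shape)
    male = 1.0 - np.power(1.0 - female, MALE_FEMALE_HAZARD_RATIO)
    return MortalitySchedule(ages=ages, male=np.clip(male, 0.0, 1.0),
                             female=np.clip(female, 0.0, 1.0),
                             male_fraction=male_fraction)


def split_mixed_dentition(schedule: IncidenceSchedule, age: float,
                          total: float | None = None,
                          low_income: bool = True) -> tuple[float, float]:
    """Split the incidence rate at ``age`` into (deciduous, permanent).

    ``total`` overrides the schedule's own rate (useful for already-adjusted
    rates); the two parts always sum to the total.  Raises
    :class:`ScheduleRangeError` outside the schedule's age range.
    """
    share = schedule.deciduous_share_at(age)
    if total is None:
        total = schedule.rate_at(age, low_income=low_income)
    return total * share, total * (1.0 - share)
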