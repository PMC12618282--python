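import numpy as np
import pytest

from cariescea.parameters import (
    CohortSpec,
    EconSettings,
    ModelConfig,
    builtin_config,
)
from cariescea.synthetic_epi import (
    IncidenceSchedule,
    MortalitySchedule,
    make_incidence_schedule,
    make_mortality_schedule,
)


@pytest.fixture(scope="session")
def incidence():
    return make_incidence_schedule(seed=1)


@pytest.fixture(scope="session")
def mortality():
    return make_mortality_schedule(seed=1)


@pytest.fixture
def config_2a():
    return builtin_config("2a")


def small_config(start_age=6.0, size=1000, horizon=2, incidence_rate=0.2,
                 mortality_rate=0.01, **overrides) -> ModelConfig:
    """Tiny single-cohort config with flat hand-set rates."""
    ages = np.arange(0.0, 26.0)
    flat = np.full(ages.shape, incidence_rate)
    inc = IncidenceSchedule(ages=ages, general=flat, low_income=flat,
                            low_income_ratio=1.0)
    mort = MortalitySchedule(ages=ages, male=np.full(ages.shape, mortality_rate),
                             female=np.full(ages.shape, mortality_rate))
    kwargs = dict(
        cohort=CohortSpec("test", (start_age,), size, size),
        horizon_years=horizon, incidence=inc, mortality=mort,
        econ=EconSettings(),
    )
    kwargs.update(overrides)
    return ModelConfig(**kwargs)
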