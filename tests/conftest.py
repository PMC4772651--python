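import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from censuslife import (
    LifeTable,
    default_config,
    simulate_population,
    survivorship,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def recovery_config():
    """Clean study conditions for parameter recovery: the reference
    schedule, 5000 founding births, moderate censoring, no disappearances,
    every newborn sexed."""
    return default_config(
        n_births=5000, seed=1, annual_disappear_prob=0.0, prob_unknown_sex=0.0
    )


@pytest.fixture(scope="session")
def recovery_population(recovery_config):
    return simulate_population(recovery_config)


@pytest.fixture(scope="session")
def rich_population():
    """A smaller population exercising every generator feature: immigrants,
    sex-biased disappearance, partial observation, unsexed newborns."""
    cfg = default_config(
        n_births=1500,
        seed=7,
        n_immigrants=150,
        immigrant_age_dist=[0.0, 0.3, 0.3, 0.2, 0.1, 0.1, 0.0, 0.0, 0.0, 0.0],
        obs_fraction_law=("beta", 8.0, 2.0),
    )
    return cfg, simulate_population(cfg)


@pytest.fixture()
def micro_table():
    """The two-class table whose statistics are all closed-form:
    l = [1, 1/2], m = [0, 2]."""
    return LifeTable(
        sex="F",
        q=np.array([0.5, 1.0]),
        l=np.array([1.0, 0.5]),
        m=np.array([0.0, 2.0]),
        N_q=np.array([10.0, 5.0]),
        N_m=np.array([4.0, 4.0]),
        omega=1,
    )


@pytest.fixture(scope="session")
def table_factory():
    """Factory for random valid life tables with an aperiodic fertility
    schedule (fertility positive from a random maturity age onward, so the
    Leslie matrix is primitive and the dominant root is the Perron root)."""

    def make(rng: np.random.Generator, n_min: int = 3, n_max: int = 12) -> LifeTable:
        n = int(rng.integers(n_min, n_max + 1))
        q = rng.uniform(0.02, 0.6, size=n)
        maturity = int(rng.integers(0, n - 1))
        m = np.zeros(n)
        m[maturity:] = rng.uniform(0.05, 1.5, size=n - maturity)
        l = survivorship(q)[:n]
        return LifeTable(
            sex="F",
            q=q,
            l=l,
            m=m,
            N_q=rng.uniform(5, 200, size=n),
            N_m=rng.uniform(1, 150, size=n),
            omega=n - 1,
        )

    return make
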