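import numpy as np
import pandas as pd
import pytest

from bmigrowth.cohort import Cohort
from bmigrowth.simulate import (
    SimulationConfig,
    TrueParams,
    make_scenario,
    simulate_bmi,
    simulate_schedule,
)
from bmigrowth.bases import BasisSpec


@pytest.fixture
def tiny_visits():
    """Three well-formed visits for one child."""
    return pd.DataFrame(
        {
            "subject_id": ["s1", "s1", "s1"],
            "sex": ["F", "F", "F"],
            "age_years": [1.1, 6.0, 14.2],
            "bmi": [17.0, 15.9, 21.5],
        }
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Default-sized synthetic cohort (both sexes, no genetic effects)."""
    cohort, genotypes, true = make_scenario("null", seed=20)
    return cohort, genotypes, true


@pytest.fixture(scope="session")
def small_female_cohort():
    """A 250-subject female stratum for fitting tests."""
    cohort, genotypes, true = make_scenario("null", sex="female", n_female=250, seed=21)
    return cohort, genotypes, true


def reduced_null_truth(**over):
    """Generative truth matching a small polynomial LMM (used by fast
    simulation tests): cubic fixed curve, random intercept+slope."""
    base = dict(
        scale="ln",
        basis=BasisSpec(kind="polynomial", degree=3, center=8.0),
        beta_female=np.array([2.83, 0.021, 0.0018, -0.00006]),
        beta_male=np.array([2.83, 0.021, 0.0018, -0.00006]),
        random_kind="linear",
        G=np.array([[0.010, 0.00075], [0.00075, 0.000225]]),
        sigma=0.04,
        phi=0.0,
        error="gaussian",
    )
    base.update(over)
    return TrueParams(**base)


@pytest.fixture
def reduced_cohort():
    """Fast 4-wave cohort of 150 children from the reduced truth."""
    cfg = SimulationConfig(
        n_male=0,
        n_female=150,
        wave_ages=(1.0, 6.0, 10.0, 17.0),
        attendance=(1.0, 1.0, 1.0, 1.0),
        age_jitter_sd=(0.1, 0.2, 0.2, 0.25),
        seed=31,
    )
    sk = simulate_schedule(cfg)
    true = reduced_null_truth()
    return simulate_bmi(sk, None, true, seed=32), true
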