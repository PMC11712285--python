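import numpy as np
import pandas as pd
import pytest

from lpisim import (
    SamplingSpec,
    ScenarioSpec,
    build_trajectory,
    degrade_sampling,
    simulate_populations,
)
from lpisim.changepoint import profile_intervention_year


@pytest.fixture(scope="session")
def recovery_spec() -> ScenarioSpec:
    return ScenarioSpec("extreme", "recovery")


@pytest.fixture(scope="session")
def noise_free_recovery(recovery_spec):
    """Noise-free, fully observed populations under extreme decline + recovery."""
    traj = build_trajectory(recovery_spec)
    sampling = SamplingSpec(obs_noise_sd=0.0, seed=101)
    return simulate_populations(traj, 20, sampling)


def _stochastic_recovery_fits(historical_class: str, n_reps: int = 20) -> pd.DataFrame:
    """Profile fits on replicated degraded noisy recovery data, 500 species.

    The study conditions: default observation noise (0.1 log10 units),
    default monitoring imperfection (mean span 15 y, fullness 0.7),
    end year 2050, candidate grid 2010-2045.
    """
    from lpisim.config import ExperimentConfig
    from lpisim.experiment import run_cell

    cfg = ExperimentConfig(
        historical_classes=(historical_class,),
        future_scenarios=("recovery",),
        sizes=(500,),
        end_years=(2050,),
        replicates=n_reps,
        master_seed=20250920,
    )
    rows = [
        run_cell(cfg, historical_class, "recovery", 500, 2050, r) for r in range(n_reps)
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def stochastic_recovery_extreme() -> pd.DataFrame:
    return _stochastic_recovery_fits("extreme")


@pytest.fixture(scope="session")
def stochastic_recovery_small() -> pd.DataFrame:
    return _stochastic_recovery_fits("small")
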