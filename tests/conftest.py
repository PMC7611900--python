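import numpy as np
import pytest

from rsadapt.synthetic_trials import (
    ScenarioConfig,
    calibrate_model_params,
    simulate_trial,
)


@pytest.fixture(scope="session")
def table1_scenario():
    """Reference scenario: 25/25/70, 10% sensitive patients."""
    return ScenarioConfig(
        n_patients=1000,
        control_rate=0.25,
        nonsensitive_treated_rate=0.25,
        sensitive_treated_rate=0.70,
        sensitive_fraction=0.10,
    )


@pytest.fixture(scope="session")
def small_scenario():
    """Cheap scenario for pipeline wiring tests (few covariates)."""
    return ScenarioConfig(
        n_patients=300,
        control_rate=0.25,
        nonsensitive_treated_rate=0.25,
        sensitive_treated_rate=0.70,
        sensitive_fraction=0.15,
        n_covariates=20,
        n_sensitive_covariates=5,
    )


@pytest.fixture(scope="session")
def small_trial(small_scenario):
    params = calibrate_model_params(small_scenario)
    return simulate_trial(small_scenario, params, seed=424)


@pytest.fixture(scope="session")
def null_trial():
    sc = ScenarioConfig(
        n_patients=300,
        control_rate=0.3,
        nonsensitive_treated_rate=0.3,
        sensitive_fraction=0.0,
        n_covariates=15,
    )
    return simulate_trial(sc, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
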