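import numpy as np
import pandas as pd
import pytest

from riverch4.synth import TruthParams, generate_network, simulate_observations

#: small learner settings so unit tests stay fast
SMALL_LEARNERS = {
    "forest": {"n_estimators": 60},
    "boosting": {"n_estimators": 100},
}


def single_signal_params(seed: int, *, beta: float = 0.5, noise: float = 0.3) -> TruthParams:
    """A world where ln flux depends on ln TP only (no class enrichment, so
    ln TP is a single normal and recovery oracles are closed-form)."""
    return TruthParams(
        seed=seed,
        intercept=-1.0,
        beta_log_tp=beta,
        beta_log_nh4=0.0,
        beta_log_tn=0.0,
        beta_log_no3=0.0,
        beta_temp=0.0,
        noise_sd=noise,
        enrichment_multipliers={"urban": 1.0, "cropland": 1.0, "dense": 1.0, "pristine": 1.0},
    )


@pytest.fixture(scope="session")
def default_params() -> TruthParams:
    return TruthParams(seed=7)


@pytest.fixture(scope="session")
def observations(default_params) -> pd.DataFrame:
    return simulate_observations(600, default_params)


@pytest.fixture(scope="session")
def network(default_params):
    return generate_network(6, 5, default_params)


@pytest.fixture(scope="session")
def reaches(network) -> pd.DataFrame:
    return network[0]


@pytest.fixture(scope="session")
def cells(network) -> pd.DataFrame:
    return network[1]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
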