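import numpy as np
import pandas as pd
import pytest

from survecon.cohort import ModelSettings
from survecon.config import default_config
from survecon.fitting import ParametricSurvivalModel


@pytest.fixture
def config():
    return default_config()


@pytest.fixture
def settings():
    return ModelSettings()


def make_model(family: str, shape: float, scale: float, n_obs: int = 100) -> ParametricSurvivalModel:
    """A survival model with given parameters (information criteria unused)."""
    return ParametricSurvivalModel(
        family=family, shape=shape, scale=scale, loglik=0.0, aic=0.0, bic=0.0, n_obs=n_obs
    )


@pytest.fixture
def exponential_pair():
    """PFS hazard 0.1/month, OS hazard 0.05/month (closed-form oracles)."""
    return make_model("exponential", 1.0, 10.0), make_model("exponential", 1.0, 20.0)


@pytest.fixture
def three_event_ipd():
    return pd.DataFrame({"time_months": [1.0, 2.0, 3.0], "event": [1, 1, 1]})


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
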