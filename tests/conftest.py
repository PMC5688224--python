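import numpy as np
import pytest

from quietstance.biomechanics import build_anthropometry
from quietstance.muscle import MuscleParams, PassiveElasticParams
from quietstance.simulator import RunConfig

THETA0 = np.array([-0.1, 0.2, -0.2])


@pytest.fixture(scope="session")
def params():
    return build_anthropometry(1.80, 80.0)


@pytest.fixture(scope="session")
def theta0():
    return THETA0.copy()


@pytest.fixture(scope="session")
def muscle_params():
    return MuscleParams()


@pytest.fixture(scope="session")
def passive():
    return PassiveElasticParams.published()


def noise_free_config(**kw) -> RunConfig:
    """Run configuration with every stochastic channel silenced."""
    kw.setdefault("muscle", MuscleParams(sigma_m=0.0))
    return RunConfig(sigma_theta=0.0, sigma_theta_dot=0.0,
                     sigma_lambda_dot=0.0, sigma_p_dot=0.0, sigma_p_ddot=0.0,
                     sigma_o=0.0, **kw)


@pytest.fixture
def noise_free():
    return noise_free_config
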