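import numpy as np
import pytest

from mhspc_cea import ModelSettings, WeibullSurvival, default_config


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def enza_pfs():
    return WeibullSurvival(shape=1.131400, scale=0.007900)


@pytest.fixture(scope="session")
def enza_os():
    return WeibullSurvival(shape=1.426021, scale=0.001476)


@pytest.fixture(scope="session")
def settings():
    return ModelSettings()


@pytest.fixture(scope="session")
def base_outcomes(config):
    from mhspc_cea import evaluate_all

    return evaluate_all(config)
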