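import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mripbpk.dce import AcquisitionProtocol
from mripbpk.pbpk import PlasmaPKParams, TumorPBPKParams
from mripbpk.synthetic import NoiseModel

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_params() -> TumorPBPKParams:
    return TumorPBPKParams()


@pytest.fixture(scope="session")
def plasma() -> PlasmaPKParams:
    return PlasmaPKParams()


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def zero_noise() -> NoiseModel:
    return NoiseModel(dce_signal_cv=0.0, obs_cv=0.0, aif_variability=0.0)


@pytest.fixture(scope="session")
def six_day_grid() -> np.ndarray:
    return np.linspace(0.0, 144.0 * 60.0, 300)
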