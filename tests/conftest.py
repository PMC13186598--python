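import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

from slopebench import CovarianceSpec, SharedErrorParams

# Study conditions used throughout: subtractive sweep moments (aim-report
# group) and the shared-error population parameterization.
PAPER_SPEC_AE = CovarianceSpec(mean_x=25.0, mean_y=5.0, sd_x=2.5, sd_y=2.5, rho=0.0)
PAPER_SHARED = SharedErrorParams(r=30.0, p_i=0.65, mu_E=12.0, sigma_E=4.0,
                                 tau_I=2.0, tau_E=4.0)


@pytest.fixture(scope="session")
def spec_ae() -> CovarianceSpec:
    return PAPER_SPEC_AE


@pytest.fixture(scope="session")
def shared_params() -> SharedErrorParams:
    return PAPER_SHARED


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
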