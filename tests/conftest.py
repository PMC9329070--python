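import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pahfate as pf
import pahfate.synthetic_data as sd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def registry():
    return pf.default_registry()


@pytest.fixture(scope="session")
def paper_like_noiseless():
    """Shipped scenario with measurement noise disabled."""
    return sd.scenario_paper_like(noise_cv=0.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_conc(paper_like_noiseless):
    sc = paper_like_noiseless
    return sd.simulate_incubation(sc.design, sc.fate)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
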