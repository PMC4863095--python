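import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_topology():
    from codespectrum import build_topology

    return build_topology()


@pytest.fixture(scope="session")
def small_topology():
    from codespectrum import build_topology

    return build_topology(3, 3)
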