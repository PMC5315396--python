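import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    from aawall.params import load_parameters

    return load_parameters()


@pytest.fixture(scope="session")
def kin(params):
    return params.kinetic


@pytest.fixture(scope="session")
def mech(params):
    return params.mechanical


@pytest.fixture(scope="session")
def coarse_geom():
    from aawall.geometry import build_initial_geometry

    return build_initial_geometry(2.0, n_y=16, nx_media=3, nx_adv=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234567)
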