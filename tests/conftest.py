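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

import rhodotune as rt


@pytest.fixture(scope="session")
def wt_geometry():
    """Planar all-trans chain with the wild-type-like BLA target."""
    return rt.make_chain_geometry(bla_target=0.1160)


@pytest.fixture(scope="session")
def charge_model():
    return rt.ChromophoreChargeModel.default()


@pytest.fixture(scope="session")
def excitation_table():
    return rt.make_excitation_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
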