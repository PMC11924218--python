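import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from marinp.assay_spectra import SampleChemistry
from marinp.cnt_model import CNTParams, WATER_ICE_DEFAULT
from marinp.synthetic_data import SimConfig


@pytest.fixture(scope="session")
def thermo():
    return WATER_ICE_DEFAULT


@pytest.fixture(scope="session")
def organism_params():
    """Default synthetic-organism truth (broad contact-angle distribution)."""
    return SimConfig().true_params


@pytest.fixture(scope="session")
def chemistry():
    return SampleChemistry("synthetic-organism", c_tccho=5e-3, toc=2e-2)


@pytest.fixture
def small_config():
    """Small, fast simulation setup for unit tests."""
    return SimConfig(seed=11, n_droplets=300, grid_shape=(6, 8), n_timesteps=8,
                     n_observations=40)
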