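import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from meththerm import CircuitParams, FixedModel, PKParams, ThermoParams
from meththerm.synthetic_data import DEFAULT_SCENARIO, DesignSpec, NoiseSpec

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pk():
    return PKParams()


@pytest.fixture(scope="session")
def thermo():
    return ThermoParams()


@pytest.fixture(scope="session")
def design():
    return DesignSpec()


@pytest.fixture(scope="session")
def vehicle_truth():
    return DEFAULT_SCENARIO[0.0]


@pytest.fixture(scope="session")
def fixed_model():
    """Fixed model whose circuit weights equal the vehicle generating truth."""
    return FixedModel()


@pytest.fixture(scope="session")
def iid_noise():
    """Noise mode exactly matching the iid-Gaussian likelihood assumption."""
    return NoiseSpec(noise_sd=0.3, ar1=0.0, baseline_sd=0.0)


@pytest.fixture(scope="session")
def meth5_series(vehicle_truth, design, iid_noise):
    """One Meth-5/vehicle synthetic group, fixed seed, iid noise."""
    from meththerm.synthetic_data import generate_group

    series, _ = generate_group(
        vehicle_truth, design, iid_noise, sb_dose=0.0, meth_dose=5.0,
        rng=np.random.default_rng(101),
    )
    return series
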