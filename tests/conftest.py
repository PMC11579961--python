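import numpy as np
import pytest

from corallight import (
    LightParams,
    ModelConfig,
    OrbitConfig,
    SyntheticGradientSpec,
    synth_scenario,
)


@pytest.fixture(scope="session")
def orbit():
    """Default (modern) orbital configuration."""
    return OrbitConfig()


@pytest.fixture(scope="session")
def circular_orbit():
    """Zero-eccentricity orbit: exact hemispheric/seasonal symmetry."""
    return OrbitConfig(eccentricity=0.0)


@pytest.fixture(scope="session")
def default_config():
    """The headline model configuration (E_k=50, k_par*z=0.75, depth 15 m)."""
    return ModelConfig()


@pytest.fixture
def warm_flat_scenario():
    """Latitudinally constant, unlimiting 26 degC ocean (sensitivity setting)."""
    spec = SyntheticGradientSpec(
        t_eq_cold=26.0, t_pole_cold=26.0, t_eq_warm=26.0, t_pole_warm=26.0,
        shape_exponent=1.0,
    )
    return synth_scenario(spec, name="flat-26C")


@pytest.fixture
def no_darkday_light():
    """Light parameters with the dark-day rule disabled."""
    return LightParams(e_lim=None, tolerance_days=None)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)
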