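import numpy as np
import pytest

from kneesim.solver import (
    SolverSettings,
    build_default_model,
    build_symmetric_model,
    reference_configuration,
)


@pytest.fixture(scope="session")
def default_settings():
    return SolverSettings()


@pytest.fixture(scope="session")
def coarse_settings():
    """Coarse flexion grid for unit tests that only need a short sweep."""
    return SolverSettings(flexion_step_deg=10.0)


@pytest.fixture(scope="session")
def nominal_model(default_settings):
    """Default synthetic model with its reference configuration established."""
    model = build_default_model()
    reference_configuration(model, default_settings)
    return model


@pytest.fixture(scope="session")
def symmetric_model(default_settings):
    model = build_symmetric_model()
    reference_configuration(model, default_settings)
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
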