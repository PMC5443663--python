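import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_model():
    from ormia.experiments import ExperimentConfig

    return ExperimentConfig().model()


@pytest.fixture(scope="session")
def calibration_curve(default_model):
    """Measured IVAD-vs-azimuth sigmoid, shared across recovery tests."""
    from ormia.experiments import calibrate_directionality

    return calibrate_directionality(default_model, seed=11)
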