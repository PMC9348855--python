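import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import naivedyn as nd

settings.register_profile(
    "ci", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cd4_params():
    return nd.reference_params("CD4", "age_loss")


@pytest.fixture(scope="session")
def cd8_params():
    return nd.reference_params("CD8", "age_loss")


@pytest.fixture(scope="session")
def cd4_influx():
    return nd.reference_influx("CD4")


@pytest.fixture(scope="session")
def cd8_influx():
    return nd.reference_influx("CD8")


@pytest.fixture(scope="session")
def neonatal_modifier():
    return nd.reference_neonatal_modifier()


@pytest.fixture()
def zero_influx():
    z = lambda t: np.zeros_like(np.asarray(t, dtype=float))
    return (z, z)
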