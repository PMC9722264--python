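import numpy as np
import pytest

from cortexwave import (
    FieldGeometry,
    SimConfig,
    generate_spontaneous_events,
    render_photometry,
)


@pytest.fixture(scope="session")
def geometry():
    return FieldGeometry()


@pytest.fixture(scope="session")
def swa_config():
    return SimConfig(duration_s=600.0, seed=3)


@pytest.fixture(scope="session")
def swa_ground_truth(swa_config, geometry):
    return generate_spontaneous_events(swa_config, geometry)


@pytest.fixture(scope="session")
def swa_traces(swa_ground_truth, geometry, swa_config):
    return render_photometry(swa_ground_truth, geometry, swa_config)


def pytest_configure(config):
    np.seterr(all="ignore")
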