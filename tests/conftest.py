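import numpy as np
import pytest

from saccadeye.depth import build_calibration
from saccadeye.geometry import GeometryConfig, build_eye_pair


@pytest.fixture(scope="session")
def eye_pair():
    """Default mirror-symmetric binocular sampling matrix."""
    return build_eye_pair(GeometryConfig())


@pytest.fixture(scope="session")
def calibration(eye_pair):
    """Noise-free forward-model calibration table (shared across tests)."""
    return build_calibration(eye_pair)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
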