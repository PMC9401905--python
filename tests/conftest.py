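import numpy as np
import pytest

from uavcal import CameraProfile
from uavcal.scene import make_endmembers, scaled_camera

#: Nominal reflectances of the eight-panel grayscale ladder.
PANEL_REFLECTANCES = np.array([0.03, 0.06, 0.12, 0.24, 0.36, 0.48, 0.56, 0.80])


@pytest.fixture(scope="session")
def camera():
    """Reference 12-band camera with synthetic Gaussian responses."""
    return CameraProfile.reference(with_responses=True)


@pytest.fixture(scope="session")
def small_camera():
    """Reference bands/FOV on a reduced pixel grid for fast rendering."""
    return scaled_camera()


@pytest.fixture(scope="session")
def endmembers():
    return make_endmembers(seed=1)


@pytest.fixture
def panel_reflectances():
    return PANEL_REFLECTANCES.copy()
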