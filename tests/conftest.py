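import numpy as np
import pytest
from hypothesis import settings

from morphodyn.contours import Outline

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def disk_mask():
    """Rasterised disk of radius 20 centred at (25, 25) in a 50x50 grid."""
    yy, xx = np.mgrid[0:50, 0:50]
    return ((xx - 25) ** 2 + (yy - 25) ** 2 <= 20 ** 2).astype(np.uint8)


@pytest.fixture
def finger_mask():
    """Disk of radius 20 with a 3-px-wide, 15-px-long finger: the phantom
    for protrusion-preserving seeding."""
    yy, xx = np.mgrid[0:80, 0:80]
    m = ((xx - 30) ** 2 + (yy - 40) ** 2 <= 20 ** 2).astype(np.uint8)
    m[39:42, 50:65] = 1
    return m


@pytest.fixture
def bright_disk():
    """Bright disk (200) on dark background (10), radius 30 in 100x100."""
    yy, xx = np.mgrid[0:100, 0:100]
    return np.where((xx - 50) ** 2 + (yy - 50) ** 2 <= 30 ** 2, 200.0, 10.0)


@pytest.fixture
def circle():
    return Outline.circle(0.0, 0.0, 10.0, 64)
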