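import numpy as np
import pytest

from cordmotor.synthetic import make_region_atlas


@pytest.fixture(scope="session")
def circle_atlas():
    """Circular binary atlas on an even grid (exact 4-fold symmetry)."""
    return make_region_atlas((24, 24), (10.0, 10.0))


@pytest.fixture(scope="session")
def small_atlas():
    """Small elliptical binary atlas for fast phantom tests."""
    return make_region_atlas((16, 16), (6.0, 5.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
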