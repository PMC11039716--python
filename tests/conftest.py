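import numpy as np
import pytest

from geoppe import ImageGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_geometry(rng, max_size=6, rotate=True):
    """A random valid geometry with a proper-rotation direction matrix."""
    from scipy.stats import special_ortho_group

    size = tuple(int(s) for s in rng.integers(1, max_size + 1, size=3))
    spacing = rng.uniform(0.5, 4.0, size=3)
    origin = rng.uniform(-50.0, 50.0, size=3)
    direction = special_ortho_group.rvs(3, random_state=rng) if rotate else np.eye(3)
    return ImageGeometry(origin=origin, spacing=spacing, direction=direction, size=size)


@pytest.fixture
def identity_geom():
    return ImageGeometry(origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0), size=(4, 4, 4))
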