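import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gelscope as g

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def one_vessel_phantom():
    """Single centred vessel with a wall marker exactly on the boundary."""
    spec = g.PhantomSpec(
        width_px=96,
        height_px=96,
        vessels=[g.Vessel((48, 48), 10, 3)],
        layers=[
            g.Layer("GLUT1", 0.0, 2.0, 100.0),
            g.Layer("CollagenIV", 3.0, 2.0, 80.0),
        ],
        background_rate=0.0,
        seed=7,
    )
    image, mask, truth = g.make_vessel_phantom(spec)
    return spec, image, mask, truth


@pytest.fixture(scope="session")
def small_cell_field():
    image, mask = g.make_cell_field(
        n_cells=40, shape=(160, 160), mean_area_px=80.0, area_cv=0.25, seed=11
    )
    return image, mask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_blob(rng, shape=(32, 32), n_seeds=3, grow=30):
    """Random connected-ish binary object for ring-algebra property tests."""
    from scipy import ndimage

    obj = np.zeros(shape, dtype=bool)
    pts = rng.integers(8, shape[0] - 8, size=(n_seeds, 2))
    obj[pts[:, 0], pts[:, 1]] = True
    for _ in range(grow // 10):
        obj = ndimage.binary_dilation(obj, iterations=2)
    return obj
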