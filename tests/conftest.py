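import numpy as np
import pytest

from etmap.fixtures import SceneSpec, make_color_scale
from etmap.raster import Affine, Raster
from etmap.tseb import MicrometRecord, TSEBParameters


@pytest.fixture(scope="session")
def scale():
    return make_color_scale()


@pytest.fixture(scope="session")
def met():
    return MicrometRecord(t_air=25.0, wind=2.0, pressure=1010.0, e_a=12.0, s_dn=800.0)


@pytest.fixture(scope="session")
def params():
    return TSEBParameters()


@pytest.fixture(scope="session")
def small_scene():
    # coarse resolution keeps per-pixel solves cheap in unit tests
    return SceneSpec(width=16.0, height=16.0, resolution=0.25, seed=3)


@pytest.fixture(scope="session")
def flight(tmp_path_factory):
    """One simulated 60 s flight shared across the session."""
    from etmap.fixtures import simulate_flight

    out = tmp_path_factory.mktemp("flight")
    spec = SceneSpec(seed=7)
    return simulate_flight(spec, out, duration=60.0)


@pytest.fixture
def rgb_raster():
    """A 60x60 synthetic RGB scene: green patch left, gray soil right."""
    rng = np.random.default_rng(11)
    img = np.zeros((3, 60, 60), dtype=np.uint8)
    img[:, :, :] = 120  # gray soil
    img[0, :, :30] = 60
    img[1, :, :30] = 160
    img[2, :, :30] = 50
    img += rng.integers(0, 5, img.shape).astype(np.uint8)
    return Raster(values=img, transform=Affine.from_origin(0.0, 6.0, 0.1, 0.1), crs="LOCAL")
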