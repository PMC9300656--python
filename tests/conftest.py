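import numpy as np
import pytest

from holotrack import DEFAULT_OPTICS, NoiseModel, SceneSpec, ZGrid
from holotrack.synthetic import forward_hologram


@pytest.fixture(scope="session")
def optics():
    return DEFAULT_OPTICS


@pytest.fixture(scope="session")
def single_bead_scene(optics):
    """Noisy forward-model hologram of one bead at sub-pixel ground truth,
    with its background and the truth table."""
    x0 = 128 * optics.pixel_spacing + 33.0
    y0 = 128 * optics.pixel_spacing - 47.0
    z0 = 10_037.0
    scene = SceneSpec(beads=((x0, y0, z0),), shape=(256, 256), seed=11)
    holo, bg, truth = forward_hologram(scene, optics, NoiseModel(kind="poisson"))
    return holo, bg, truth


@pytest.fixture(scope="session")
def zgrid_10um():
    return ZGrid.from_range(7_000.0, 13_000.0, 100.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
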