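import numpy as np
import pytest
from hypothesis import settings

from veinquant.image import CellMap
from veinquant.synthetic import VeinConfig, generate_vein

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

_VEIN_CACHE: dict = {}


def cached_vein(config: VeinConfig):
    """Generate-or-reuse a synthetic vein; keyed by the full config."""
    key = repr(config)
    if key not in _VEIN_CACHE:
        _VEIN_CACHE[key] = generate_vein(config)
    return _VEIN_CACHE[key]


@pytest.fixture(scope="session")
def default_vein():
    """A typical noise-free mature vein with full ground truth."""
    return cached_vein(VeinConfig(seed=3, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_vein():
    """The same vein at the default noise level."""
    return cached_vein(VeinConfig(seed=3))


@pytest.fixture()
def stripes_map():
    """Three horizontal stripes A|B|C."""
    labels = np.zeros((9, 6), dtype=np.int64)
    labels[0:3] = 1
    labels[3:6] = 2
    labels[6:9] = 3
    return CellMap(labels, 0.2, {1: "XY", 2: "SE", 3: "CC"})


@pytest.fixture()
def corner_touch_map():
    """Two cells meeting only at a pixel corner (diagonal contact)."""
    labels = np.zeros((4, 4), dtype=np.int64)
    labels[:2, :2] = 1
    labels[2:, 2:] = 2
    return CellMap(labels, 0.5, {1: "PP", 2: "SE"})


def random_label_map(rng: np.random.Generator, shape=(40, 40), n_cells=6, pixel=0.25):
    """Small nearest-seed label map with random cell types (no background)."""
    pts = rng.uniform(0, shape[0], size=(n_cells, 2)) * [
        shape[0] / shape[0],
        shape[1] / shape[0],
    ]
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()], axis=1)
    d = ((coords[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    labels = (d.argmin(axis=1) + 1).reshape(shape)
    types = {
        i + 1: t
        for i, t in enumerate(
            rng.choice(["XY", "SE", "CC", "PP", "BS", "OTHER"], size=n_cells)
        )
    }
    return CellMap(labels, pixel, types)
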