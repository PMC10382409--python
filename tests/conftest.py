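import numpy as np
import pytest

from foveal3d.core import Volume, NodeLabelMap


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def sphere_labels():
    """A 32^3 label map with one 14 mm sphere (node id 1) at the center."""
    shape = (32, 32, 32)
    g = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((gi - 15.5) ** 2 for gi in g)
    labels = (d2 <= 7.0 ** 2).astype(np.int32)
    return NodeLabelMap(labels=labels)


def make_ellipsoid_mask(shape, center, semi_axes, spacing=(1.0, 1.0, 1.0)):
    g = np.meshgrid(*[np.arange(s) * sp for s, sp in zip(shape, spacing)],
                    indexing="ij")
    return sum(((gi - c) / a) ** 2
               for gi, c, a in zip(g, center, semi_axes)) <= 1.0


@pytest.fixture
def smooth_volume():
    """A band-limited synthetic volume (sum of low-frequency cosines)."""
    shape = (24, 24, 24)
    g = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    data = (50.0 * np.cos(2 * np.pi * g[0] / 24)
            + 30.0 * np.sin(2 * np.pi * g[1] / 16)
            + 20.0 * np.cos(2 * np.pi * g[2] / 12) + 40.0)
    return Volume(data=data.astype(np.float32), spacing=(2.0, 1.0, 1.0))
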