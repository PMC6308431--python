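import numpy as np
import pytest
from skimage.draw import circle_perimeter

from blastograde import imaging, segmentation, synthetic


def make_ring(radius: int, center=(240, 320), shape=(480, 640)) -> np.ndarray:
    """A 1-px rasterised circle on an empty frame (boolean edge image)."""
    img = np.zeros(shape, dtype=bool)
    rr, cc = circle_perimeter(center[0], center[1], radius, shape=shape)
    img[rr, cc] = True
    return img


@pytest.fixture(scope="session")
def microscope_render():
    """One clean grade-1 microscope-regime embryo with its ground truth."""
    spec = synthetic.SyntheticSpec(regime="microscope", grade=1, seed=7)
    return synthetic.render_blastocyst(spec)


@pytest.fixture(scope="session")
def microscope_segmentation(microscope_render):
    raw, truth = microscope_render
    std = imaging.standardize(raw)
    seg = segmentation.segment(std)
    assert seg.circle is not None
    return seg, truth


@pytest.fixture(scope="session")
def feature_dataset():
    """Separable 3-class feature surrogate (24 columns)."""
    return synthetic.generate_feature_dataset(n_per_class=100, separation=6.0, seed=11)
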