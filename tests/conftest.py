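"""Shared fixtures: small synthetic leaves and simple rendered shapes."""

import numpy as np
import pytest

from leafgrade.edges import DEFAULT_BACKGROUND, LeafImage
from leafgrade.synthetic import DEFAULT_CLASS_SPECS, LeafClassSpec, generate_leaf

#: a down-scaled leaf spec for fast unit tests on a 256-px canvas
SMALL_SPEC = LeafClassSpec(
    label="B4L", mean_rgb=(185, 140, 75), rgb_spread=7.5,
    texture_grain=5.0, texture_amplitude=0.04,
    hole_fraction=0.05, size_range=(100, 130),
)

SMALL_SPEC_NO_HOLES = LeafClassSpec(
    label="X1L", mean_rgb=(205, 175, 95), rgb_spread=10.0,
    texture_grain=1.5, texture_amplitude=0.035,
    hole_fraction=0.0, size_range=(100, 130),
)


@pytest.fixture(scope="session")
def small_leaf():
    """(image, truth) of a 256-px leaf with 5 % holes."""
    return generate_leaf(SMALL_SPEC, 256, seed=7)


@pytest.fixture(scope="session")
def small_leaf_solid():
    """(image, truth) of a hole-free 256-px leaf."""
    return generate_leaf(SMALL_SPEC_NO_HOLES, 256, seed=11)


@pytest.fixture(scope="session")
def default_leaf():
    """(image, truth) of a full-size leaf from the shipped default specs."""
    return generate_leaf(DEFAULT_CLASS_SPECS[1], 512, seed=11)


def render_mask(mask, color=(120, 160, 60)):
    """Paint a boolean mask as a flat-coloured object on the background."""
    px = np.full(mask.shape + (3,), DEFAULT_BACKGROUND[0], np.uint8)
    px[mask] = color
    return LeafImage(pixels=px)


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2
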