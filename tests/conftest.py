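import numpy as np
import pytest

from ctiq.phantoms import Ellipse, PhantomLayout, builtin_layouts
from ctiq.simulate import ImageStack, ScanCondition


@pytest.fixture(scope="session")
def ctp404():
    return builtin_layouts("ctp404")


@pytest.fixture(scope="session")
def ctp515():
    return builtin_layouts("ctp515")


@pytest.fixture
def uniform_layout():
    """Small uniform disk phantom for noise-only experiments."""
    return PhantomLayout("uniform", Ellipse("body", (0.0, 0.0), (40.0, 40.0), 100.0))


def make_stack(images, spacing_mm=0.703125, algorithm="FBP", dose=24.0, seed=0):
    """Wrap raw arrays in an ImageStack with a placeholder condition."""
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    return ImageStack(
        images=images,
        pixel_spacing_mm=spacing_mm,
        condition=ScanCondition(algorithm, dose),
        seed=seed,
    )
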