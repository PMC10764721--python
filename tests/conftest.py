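import numpy as np
import pytest

from heotsu import RGBImage, SlideSpec, generate_slide


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_slide():
    """A pink tissue disc on near-white background, no artefacts."""
    return generate_slide(SlideSpec(seed=42))


@pytest.fixture
def pen_slide_factory():
    def make(colour: str, seed: int = 7, width: int = 5):
        return generate_slide(
            SlideSpec(seed=seed, pen_strokes=((colour, width), (colour, 3)))
        )

    return make


def disc_image(h=96, w=128, colour=(0.90, 0.55, 0.71), background=0.96):
    """Hand-built slide: a hard-edged pink disc on an achromatic background."""
    img = np.full((h, w, 3), background, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.hypot(yy - h / 2, xx - w / 2) < min(h, w) * 0.3
    img[mask] = colour
    return RGBImage(img), mask
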