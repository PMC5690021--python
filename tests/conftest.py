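import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """Config sized for 64x64-or-smaller test images: N=24, M=8."""
    from setuperr import MatchConfig

    return MatchConfig(
        s=40,
        sn=0.6,
        s_sigma=0.4,
        M=8,
        mt=30000.0,
        subpixel_step_px=0.25,
        pixel_spacing_mm=0.5,
        min_valid_px=16,
    )


def make_radiograph(pixels, view="frontal", spacing=0.5, ic=None):
    from setuperr import Radiograph

    pixels = np.asarray(pixels, dtype=np.float64)
    if ic is None:
        h, w = pixels.shape
        ic = ((w - 1) / 2.0, (h - 1) / 2.0)
    return Radiograph(pixels=pixels, view=view, pixel_spacing_mm=spacing, isocenter_px=ic)


@pytest.fixture
def textured_pair(rng, small_cfg):
    """A smooth textured 48x48 reference and an identical acquisition."""
    from scipy import ndimage

    base = ndimage.gaussian_filter(rng.normal(0, 1, (48, 48)), 1.5)
    base = 20000 + 8000 * (base - base.min()) / (base.max() - base.min())
    drr = make_radiograph(base, "frontal")
    dr = make_radiograph(base.copy(), "frontal")
    return dr, drr
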