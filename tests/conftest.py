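import numpy as np
import pytest

from leafgp import (
    ImageScale,
    PotMask,
    PotRegion,
    RawImage,
    SyntheticTrayParams,
    generate_synthetic_tray,
)


@pytest.fixture
def unit_scale() -> ImageScale:
    """1 px == 1 mm, so pixel counts read directly as mm²."""
    return ImageScale(px_per_mm=1.0, marker_radius_mm=4.0)


@pytest.fixture
def small_tray():
    """A compact 2 x 2 synthetic tray with known per-pot leaf counts."""
    params = SyntheticTrayParams(
        rows=2, cols=2, width=700, height=1024, leaf_counts=(3, 5, 7, 4)
    )
    img, truth = generate_synthetic_tray(params, seed=11)
    return params, img, truth


@pytest.fixture
def noisy_tray():
    """2 x 3 tray with algae speckle and one harvested pot."""
    params = SyntheticTrayParams(
        rows=2, cols=3, width=900, height=1024,
        leaf_counts=(3, 5, 0, 7, 4, 6), harvested=(3,), n_algae_speckles=25,
    )
    img, truth = generate_synthetic_tray(params, seed=7)
    return params, img, truth


def pot_from_mask(mask: np.ndarray, index: int = 1) -> PotMask:
    h, w = mask.shape
    return PotMask(
        region=PotRegion(index=index, row=1, col=index, bbox=(0, 0, w, h)),
        mask=np.asarray(mask, dtype=bool),
    )


def raw_from_array(arr: np.ndarray, name: str = "test") -> RawImage:
    return RawImage(pixels=arr, source_name=name)
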