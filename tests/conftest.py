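from pathlib import Path

import numpy as np
import pytest

from vitrophen.segment import SegmentationConfig
from vitrophen.synthgen import SceneSpec

TESTS_DIR = Path(__file__).parent


def single_pixel_image(rgb) -> np.ndarray:
    """1×1 RGB image from a colour triple."""
    return np.array(rgb, dtype=np.uint8).reshape(1, 1, 3)


def random_mask(rng: np.random.Generator, max_side: int = 32) -> np.ndarray:
    """Random boolean mask with at least one foreground pixel."""
    h, w = rng.integers(1, max_side + 1, size=2)
    mask = rng.random((h, w)) < rng.uniform(0.05, 0.8)
    if not mask.any():
        mask[rng.integers(h), rng.integers(w)] = True
    return mask


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def scene_cfg() -> SegmentationConfig:
    """Segmentation config matched to the default synthetic canvas (360×480)."""
    spec = SceneSpec()
    h, w = spec.canvas
    return SegmentationConfig(
        crop_width=w, crop_height=h, medium_row=spec.medium_row
    )
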