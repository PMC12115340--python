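"""Plant isolation: crop, dual-channel binarisation, morphology, mask fusion.

The pipeline crops the working region, then runs two branches in parallel:

* Y branch — CMYK yellow channel, foreground where Y > ``y_threshold``
  (default 45), then a 5×5 closing followed by a 3×3 cruciform opening;
* a* branch — 8-bit offset a* channel, foreground where a8 ≤ ``a_threshold``
  (default 124, the green side; equivalent to binarise-then-invert), then
  removal of components smaller than ``fill_min_size``.

The two masks are OR-ed and used to zero the background of the cropped image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Optional, Tuple

import numpy as np
from scipy import ndimage

from vitrophen import colour
from vitrophen.errors import (
    ConfigurationError,
    DimensionMismatchError,
    EmptyMaskWarning,
)

#: 3×3 cruciform (4-connected cross) structuring element.
CRUCIFORM = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

#: 8-connectivity structure used for component labelling throughout.
CONN8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationConfig:
    """Run configuration for :func:`segment_plant` and its stages.

    ``crop_anchor`` is the (row, col) of the crop window's top-left corner;
    ``None`` centres the window. ``medium_row`` (optional) is the row index
    of the medium surface in the *cropped* frame, used for the above/below
    area split downstream.
    """

    crop_width: int = 2800
    crop_height: int = 2600
    crop_anchor: Optional[Tuple[int, int]] = None
    y_threshold: int = 45
    a_threshold: int = 124
    close_kernel: int = 5
    fill_min_size: int = 50
    medium_row: Optional[int] = None

    def __post_init__(self) -> None:
        if self.crop_width < 1 or self.crop_height < 1:
            raise ConfigurationError("crop dimensions must be positive")
        for name in ("y_threshold", "a_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ConfigurationError(f"{name}={v} outside [0, 255]")
        if self.close_kernel < 3 or self.close_kernel % 2 == 0:
            raise ConfigurationError("close_kernel must be odd and ≥ 3")
        if self.fill_min_size < 1:
            raise ConfigurationError("fill_min_size must be ≥ 1")

    def with_overrides(self, **kwargs) -> "SegmentationConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SegmentationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = dict(mapping)
        if cfg.get("crop_anchor") is not None:
            cfg["crop_anchor"] = tuple(cfg["crop_anchor"])
        return cls(**cfg)

    @classmethod
    def from_file(cls, path: str | Path) -> "SegmentationConfig":
        """Load from a JSON or YAML file (decided by extension)."""
        import json

        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        return cls.from_mapping(data)


def _validate_mask(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise DimensionMismatchError(f"mask must be 2-D, got shape {arr.shape}")
    return arr.astype(bool, copy=False)


def crop(img: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Crop the anchored ``crop_height × crop_width`` window out of ``img``."""
    arr = colour.validate_rgb(img)
    h, w = arr.shape[:2]
    ch, cw = cfg.crop_height, cfg.crop_width
    if ch > h:
        raise ConfigurationError(f"crop_height {ch} exceeds image height {h}")
    if cw > w:
        raise ConfigurationError(f"crop_width {cw} exceeds image width {w}")
    if cfg.crop_anchor is None:
        r0, c0 = (h - ch) // 2, (w - cw) // 2
    else:
        r0, c0 = cfg.crop_anchor
    if r0 < 0 or r0 + ch > h:
        raise ConfigurationError(
            f"crop rows [{r0}, {r0 + ch}) fall outside image height {h}"
        )
    if c0 < 0 or c0 + cw > w:
        raise ConfigurationError(
            f"crop cols [{c0}, {c0 + cw}) fall outside image width {w}"
        )
    return arr[r0 : r0 + ch, c0 : c0 + cw].copy()


def binarize(
    channel: np.ndarray,
    threshold: int,
    keep: Literal["above", "at_or_below"] = "above",
) -> np.ndarray:
    """Threshold an 8-bit channel into a boolean mask.

    ``keep="above"`` marks values strictly greater than the threshold;
    ``keep="at_or_below"`` marks values ≤ threshold, realising a
    binarise-then-invert in one step.
    """
    arr = np.asarray(channel)
    if arr.ndim != 2:
        raise DimensionMismatchError(f"channel must be 2-D, got shape {arr.shape}")
    if keep == "above":
        return arr > threshold
    if keep == "at_or_below":
        return arr <= threshold
    raise ConfigurationError(f"keep must be 'above' or 'at_or_below', got {keep!r}")


def clean_mask(mask: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Morphological cleaning: square closing, then cruciform opening.

    Dilation with the ``close_kernel`` square followed by erosion with the
    same kernel (a closing: fills pinholes, bridges 1–2 px gaps), then an
    opening with the 3×3 cross (removes isolated pixels and 1-px spurs).
    """
    if cfg is None:
        cfg = SegmentationConfig()
    m = _validate_mask(mask)
    square = np.ones((cfg.close_kernel, cfg.close_kernel), dtype=bool)
    closed = ndimage.binary_erosion(ndimage.binary_dilation(m, structure=square), structure=square)
    opened = ndimage.binary_dilation(
        ndimage.binary_erosion(closed, structure=CRUCIFORM), structure=CRUCIFORM
    )
    return opened


def fill_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Drop 8-connected foreground components with fewer than ``min_size`` pixels."""
    if min_size < 1:
        raise ConfigurationError("min_size must be ≥ 1")
    m = _validate_mask(mask)
    if min_size == 1 or not m.any():
        return m.copy()
    labels, n = ndimage.label(m, structure=CONN8)
    if n == 0:
        return m.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]


def or_masks(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    """Pixelwise logical OR of two equally sized masks."""
    a, b = _validate_mask(m1), _validate_mask(m2)
    if a.shape != b.shape:
        raise DimensionMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a | b


def segment_plant(
    img: np.ndarray, cfg: SegmentationConfig | None = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Full isolation pipeline; returns ``(mask, masked_rgb)``.

    Crops, runs the Y-channel and a*-channel branches, fuses the branch
    masks with a logical OR and zeroes background pixels of the cropped
    image. An empty final mask raises :class:`EmptyMaskWarning` (a warning,
    not an error).
    """
    if cfg is None:
        cfg = SegmentationConfig()
    work = crop(img, cfg)

    y_channel = colour.rgb_to_cmyk_channel(work, "Y")
    y_mask = clean_mask(binarize(y_channel, cfg.y_threshold, keep="above"), cfg)

    a_channel = colour.rgb_to_a8(work)
    a_mask = fill_small(
        binarize(a_channel, cfg.a_threshold, keep="at_or_below"), cfg.fill_min_size
    )

    mask = or_masks(y_mask, a_mask)
    if not mask.any():
        warnings.warn("segmentation produced an empty mask", EmptyMaskWarning)

    masked = work.copy()
    masked[~mask] = 0
    return mask, masked
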