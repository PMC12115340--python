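"""Deterministic colour-space conversions from 8-bit sRGB.

Two conversions drive segmentation and scoring:

* sRGB → CMYK (max-based formula); the yellow channel separates plant
  tissue from a blue background.
* sRGB → CIELAB under D65 / 2° observer, in both signed floating point
  (used by the greenness index) and the offset-128 8-bit encoding
  (used by the a*-channel threshold).

All 8-bit outputs are rounded half-away-from-zero so results are bit-exact
across platforms.
"""

from __future__ import annotations

import numpy as np

from vitrophen.errors import ConfigurationError

CMYK_CHANNELS = ("C", "M", "Y", "K")
LAB8_CHANNELS = ("L8", "a8", "b8")

# sRGB (IEC 61966-2-1) linear RGB -> XYZ, D65 white, 2 deg observer.
_RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
# White point is the row sums of the matrix, so RGB (255,255,255) maps to
# exactly L*=100, a*=b*=0.
_WHITE = _RGB_TO_XYZ.sum(axis=1)


def validate_rgb(img: np.ndarray) -> np.ndarray:
    """Validate an H×W×3 8-bit RGB raster and return it as uint8."""
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ConfigurationError(
            f"expected an H×W×3 RGB array, got shape {arr.shape}"
        )
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ConfigurationError("image must be at least 1×1")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ConfigurationError(f"RGB intensities must be integers, got {arr.dtype}")
    if arr.min() < 0 or arr.max() > 255:
        raise ConfigurationError("RGB intensities must lie in [0, 255]")
    return arr.astype(np.uint8, copy=False)


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (unlike numpy's banker's rounding)."""
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def rgb_to_cmyk_channel(img: np.ndarray, channel: str) -> np.ndarray:
    """Extract one CMYK channel as an 8-bit H×W image.

    With R' = R/255 etc.: K = 1 − max(R',G',B'); C = (1−R'−K)/(1−K) and
    analogously for M (green) and Y (blue). Pure black (K = 1) returns 0
    for C, M and Y by convention. The selected channel is scaled ×255 and
    rounded to the nearest integer.
    """
    if channel not in CMYK_CHANNELS:
        raise ConfigurationError(
            f"unknown CMYK channel {channel!r}; expected one of {CMYK_CHANNELS}"
        )
    rgb = validate_rgb(img).astype(np.float64) / 255.0
    k = 1.0 - rgb.max(axis=2)
    if channel == "K":
        values = k
    else:
        idx = {"C": 0, "M": 1, "Y": 2}[channel]
        denom = 1.0 - k
        with np.errstate(divide="ignore", invalid="ignore"):
            values = (1.0 - rgb[..., idx] - k) / denom
        values[denom == 0] = 0.0  # K=1 convention
    out = np.clip(round_half_away(values * 255.0), 0, 255)
    return out.astype(np.uint8)


def _srgb_to_linear(v: np.ndarray) -> np.ndarray:
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def _lab_f(t: np.ndarray) -> np.ndarray:
    eps = (6.0 / 29.0) ** 3
    return np.where(t > eps, np.cbrt(t), t / (3 * (6.0 / 29.0) ** 2) + 4.0 / 29.0)


def rgb_to_lab_signed(img: np.ndarray) -> np.ndarray:
    """Convert 8-bit sRGB to signed CIELAB (D65, 2° observer).

    Returns an H×W×3 float64 array of (L*, a*, b*); L* in [0, 100], a* and
    b* roughly in [−128, 127]. Neutral inputs (R=G=B) map to a* = b* = 0
    exactly because the white point is taken from the conversion matrix.
    """
    rgb = validate_rgb(img).astype(np.float64) / 255.0
    linear = _srgb_to_linear(rgb)
    xyz = linear @ _RGB_TO_XYZ.T
    f = _lab_f(xyz / _WHITE)
    lab = np.empty_like(xyz)
    lab[..., 0] = 116.0 * f[..., 1] - 16.0
    lab[..., 1] = 500.0 * (f[..., 0] - f[..., 1])
    lab[..., 2] = 200.0 * (f[..., 1] - f[..., 2])
    return lab


def lab_signed_to_8bit(lab: np.ndarray, channel: str) -> np.ndarray:
    """Encode one signed Lab channel into 8 bits.

    L8 = round(L*·255/100); a8 = round(a* + 128); b8 = round(b* + 128);
    all clamped to [0, 255]. The offset-128 encoding is what makes an
    a*-channel threshold such as 124 meaningful.
    """
    if channel not in LAB8_CHANNELS:
        raise ConfigurationError(
            f"unknown 8-bit Lab channel {channel!r}; expected one of {LAB8_CHANNELS}"
        )
    arr = np.asarray(lab, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ConfigurationError(
            f"expected an H×W×3 signed Lab array, got shape {arr.shape}"
        )
    if channel == "L8":
        values = arr[..., 0] * 255.0 / 100.0
    elif channel == "a8":
        values = arr[..., 1] + 128.0
    else:
        values = arr[..., 2] + 128.0
    return np.clip(round_half_away(values), 0, 255).astype(np.uint8)


def rgb_to_a8(img: np.ndarray) -> np.ndarray:
    """Shortcut: 8-bit offset a* channel straight from RGB."""
    return lab_signed_to_8bit(rgb_to_lab_signed(img), "a8")
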