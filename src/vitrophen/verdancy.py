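"""Greenness index: CIELAB chromaticity angle of the foreground, rescaled 0–100.

Foreground pixels qualify when a* < 0 and b* > 0 (strictly): green on the
green–red axis, yellow on the blue–yellow axis. Over qualifying pixels,
ā = |mean(a*)| and b̄ = mean(b*); the angle θ = arctan(ā/b̄)·180/π is mapped
linearly to an index, 0 at θ = 0° (pure chlorosis) and 100 at θ = 90°
(pure verdancy). Lightness L* never enters the score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from vitrophen import colour
from vitrophen.errors import DimensionMismatchError, UndefinedTraitError


@dataclass(frozen=True)
class GreennessResult:
    a_bar: float
    b_bar: float
    theta: float
    index: float
    n_qualifying: int


def extract_lab_pixels(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Signed (L*, a*, b*) rows for exactly the mask's foreground pixels.

    Mask membership — not non-zero testing — defines the foreground.
    Returns an (N, 3) float64 array in raster order.
    """
    rgb = colour.validate_rgb(img)
    m = np.asarray(mask).astype(bool)
    if m.shape != rgb.shape[:2]:
        raise DimensionMismatchError(
            f"mask shape {m.shape} does not match image shape {rgb.shape[:2]}"
        )
    if not m.any():
        return np.empty((0, 3), dtype=np.float64)
    lab = colour.rgb_to_lab_signed(rgb)
    return lab[m]


def qualifying_pixels(table: np.ndarray) -> np.ndarray:
    """Rows with a* < 0 and b* > 0 (strict); input order preserved."""
    arr = np.asarray(table, dtype=np.float64).reshape(-1, 3)
    if arr.shape[0] == 0:
        return arr
    keep = (arr[:, 1] < 0) & (arr[:, 2] > 0)
    return arr[keep]


def greenness_theta(table: np.ndarray) -> float:
    """Chromaticity angle θ in degrees from a table of qualifying pixels."""
    arr = np.asarray(table, dtype=np.float64).reshape(-1, 3)
    if arr.shape[0] == 0:
        raise UndefinedTraitError(
            "greenness undefined: no qualifying pixels", n_qualifying=0
        )
    a_bar = abs(float(arr[:, 1].mean()))
    b_bar = float(arr[:, 2].mean())
    return math.degrees(math.atan2(a_bar, b_bar))


def rescale_theta(theta: float) -> float:
    """Map θ ∈ [0°, 90°] linearly onto the 0–100 index."""
    if not 0.0 <= theta <= 90.0:
        raise UndefinedTraitError(f"theta {theta} outside [0, 90] degrees")
    return theta * 100.0 / 90.0


def greenness_index(img: np.ndarray, mask: np.ndarray) -> GreennessResult:
    """Full greenness computation from an image and its foreground mask."""
    table = qualifying_pixels(extract_lab_pixels(img, mask))
    return greenness_from_table(table)


def greenness_from_table(table: np.ndarray) -> GreennessResult:
    """Greenness from an already-qualified (N, 3) Lab pixel table."""
    arr = qualifying_pixels(table)
    if arr.shape[0] == 0:
        raise UndefinedTraitError(
            "greenness undefined: no qualifying pixels", n_qualifying=0
        )
    a_bar = abs(float(arr[:, 1].mean()))
    b_bar = float(arr[:, 2].mean())
    theta = math.degrees(math.atan2(a_bar, b_bar))
    return GreennessResult(
        a_bar=a_bar,
        b_bar=b_bar,
        theta=theta,
        index=rescale_theta(theta),
        n_qualifying=int(arr.shape[0]),
    )
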