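"""Shape traits from a binary mask.

Conventions (fixed so that solidity is provably in (0, 1]):

* area and convex hull area are both *pixel counts* — the hull area counts
  pixel centres inside or on the convex hull polygon of all foreground
  pixel centres;
* perimeter is the arc length of the closed outer boundary chain of each
  8-connected component, traced through boundary pixel centres (axial step
  1, diagonal step √2); a single-pixel component contributes 0;
* all retained foreground is treated as one composite object: one hull over
  all pixels, perimeter summed over components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import shapely
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial._qhull import QhullError

from vitrophen.errors import ConfigurationError, UndefinedTraitError
from vitrophen.segment import CONN8, _validate_mask


@dataclass(frozen=True)
class ShapeTraits:
    area: int
    hull_area: int
    perimeter: float
    solidity: float
    area_above: Optional[int] = None
    area_below: Optional[int] = None


def pixel_area(mask: np.ndarray) -> int:
    """Number of foreground pixels."""
    return int(np.count_nonzero(_validate_mask(mask)))


def convex_hull_area(mask: np.ndarray) -> int:
    """Pixel count of the rasterised convex hull of the foreground.

    Counts pixel centres lying inside or on the convex hull polygon of all
    foreground pixel centres. Degenerate hulls (single pixel, collinear
    pixels) count the lattice points on the hull segment.
    """
    m = _validate_mask(mask)
    pts = np.argwhere(m)
    if len(pts) == 0:
        raise UndefinedTraitError("convex hull area undefined for an empty mask")
    if len(pts) == 1:
        return 1
    try:
        hull = ConvexHull(pts.astype(np.float64))
    except QhullError:
        # All centres collinear: lexicographic extremes are the segment ends;
        # integer points on the segment = gcd(|dr|, |dc|) + 1.
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        (r0, c0), (r1, c1) = pts[order[0]], pts[order[-1]]
        return int(math.gcd(abs(int(r1 - r0)), abs(int(c1 - c0)))) + 1
    poly = shapely.Polygon(pts[hull.vertices])
    shapely.prepare(poly)
    rmin, cmin = pts.min(axis=0)
    rmax, cmax = pts.max(axis=0)
    rr, cc = np.meshgrid(
        np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1), indexing="ij"
    )
    inside = shapely.intersects_xy(poly, rr.ravel(), cc.ravel())
    return int(np.count_nonzero(inside))


# Moore neighbourhood in clockwise order starting west (row, col offsets).
_MOORE = (
    (0, -1),
    (-1, -1),
    (-1, 0),
    (-1, 1),
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
)
_MOORE_INDEX = {off: i for i, off in enumerate(_MOORE)}


def _next_on_boundary(
    fg: set, cur: Tuple[int, int], backtrack: Tuple[int, int]
) -> Optional[Tuple[Tuple[int, int], Tuple[int, int]]]:
    """Clockwise Moore scan from the backtrack pixel; returns (next, new_backtrack)."""
    start_idx = _MOORE_INDEX[(backtrack[0] - cur[0], backtrack[1] - cur[1])]
    prev = backtrack
    for k in range(1, 9):
        dr, dc = _MOORE[(start_idx + k) % 8]
        cand = (cur[0] + dr, cur[1] + dc)
        if cand in fg:
            return cand, prev
        prev = cand
    return None


def _trace_outer_boundary(fg: set, start: Tuple[int, int]) -> list:
    """Closed outer boundary chain by Moore-neighbour tracing.

    ``start`` must be the raster-first pixel of its component so that its
    west neighbour is guaranteed background. The chain begins and ends at
    ``start``; termination is when the trace re-enters ``start`` and is
    about to repeat the first move.
    """
    first = _next_on_boundary(fg, start, (start[0], start[1] - 1))
    if first is None:
        return [start]
    chain = [start]
    cur, backtrack = first
    while True:
        chain.append(cur)
        step = _next_on_boundary(fg, cur, backtrack)
        cur, backtrack = step
        if cur == start:
            peek = _next_on_boundary(fg, cur, backtrack)
            if peek is not None and peek[0] == chain[1]:
                chain.append(start)
                return chain
            chain.append(start)
            # passed through start mid-contour; keep tracing
            cur, backtrack = peek
        if len(chain) > 8 * len(fg) + 8:  # safety net; cannot trigger on valid input
            raise RuntimeError("boundary trace failed to close")


def perimeter(mask: np.ndarray) -> float:
    """Summed outer-boundary arc length over all 8-connected components."""
    m = _validate_mask(mask)
    if not m.any():
        raise UndefinedTraitError("perimeter undefined for an empty mask")
    labels, n = ndimage.label(m, structure=CONN8)
    total = 0.0
    slices = ndimage.find_objects(labels)
    for i, sl in enumerate(slices, start=1):
        comp = labels[sl] == i
        coords = np.argwhere(comp)
        fg = set(map(tuple, coords))
        start = tuple(coords[np.lexsort((coords[:, 1], coords[:, 0]))[0]])
        chain = _trace_outer_boundary(fg, start)
        for (r0, c0), (r1, c1) in zip(chain[:-1], chain[1:]):
            total += math.sqrt((r1 - r0) ** 2 + (c1 - c0) ** 2)
    return total


def solidity(mask: np.ndarray) -> float:
    """Ratio of pixel area to convex hull pixel area; in (0, 1]."""
    area = pixel_area(mask)
    if area == 0:
        raise UndefinedTraitError("solidity undefined for an empty mask")
    return area / convex_hull_area(mask)


def split_area_at_row(mask: np.ndarray, medium_row: int) -> Tuple[int, int]:
    """Foreground split at the medium level: rows < ``medium_row`` count as above."""
    m = _validate_mask(mask)
    h = m.shape[0]
    if not 0 <= medium_row <= h:
        raise ConfigurationError(
            f"medium_row {medium_row} outside [0, {h}] for a mask of height {h}"
        )
    above = int(np.count_nonzero(m[:medium_row]))
    below = int(np.count_nonzero(m[medium_row:]))
    return above, below


def compute_traits(
    mask: np.ndarray, medium_row: Optional[int] = None
) -> ShapeTraits:
    """All shape traits in one call; raises UndefinedTraitError on an empty mask."""
    area = pixel_area(mask)
    if area == 0:
        raise UndefinedTraitError("shape traits undefined for an empty mask")
    hull = convex_hull_area(mask)
    per = perimeter(mask)
    above = below = None
    if medium_row is not None:
        above, below = split_area_at_row(mask, medium_row)
    return ShapeTraits(
        area=area,
        hull_area=hull,
        perimeter=per,
        solidity=area / hull,
        area_above=above,
        area_below=below,
    )
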