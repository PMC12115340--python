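"""Independent brute-force oracles used by the test suite.

Deliberately implemented with different algorithms from the package:

* convex hull via Andrew's monotone chain + exact integer cross-product
  point-in-convex-polygon tests;
* outer-boundary perimeter via Suzuki–Abe-style border following
  (counterclockwise scans) over BFS-labelled components.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def monotone_chain_hull(points: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Convex hull vertices (counterclockwise) of integer points."""
    pts = sorted(set(map(tuple, points)))
    if len(pts) <= 2:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list = []
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return lower[:-1] + upper[:-1]


def hull_area_oracle(mask: np.ndarray) -> int:
    """Count pixel centres inside or on the hull polygon — exact integer test."""
    pts = [tuple(p) for p in np.argwhere(np.asarray(mask, dtype=bool))]
    if not pts:
        raise ValueError("empty mask")
    hull = monotone_chain_hull(pts)
    if len(hull) == 1:
        return 1
    if len(hull) == 2:
        (r0, c0), (r1, c1) = hull
        return math.gcd(abs(r1 - r0), abs(c1 - c0)) + 1

    def inside(p) -> bool:
        n = len(hull)
        for i in range(n):
            a, b = hull[i], hull[(i + 1) % n]
            cross = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
            if cross < 0:
                return False
        return True

    rs = [p[0] for p in pts]
    cs = [p[1] for p in pts]
    count = 0
    for r in range(min(rs), max(rs) + 1):
        for c in range(min(cs), max(cs) + 1):
            if inside((r, c)):
                count += 1
    return count


def _bfs_components(mask: np.ndarray) -> list[set]:
    """8-connected components by BFS flood fill (no scipy)."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    seen = np.zeros_like(m)
    comps = []
    for r in range(h):
        for c in range(w):
            if m[r, c] and not seen[r, c]:
                comp = set()
                queue = deque([(r, c)])
                seen[r, c] = True
                while queue:
                    cr, cc = queue.popleft()
                    comp.add((cr, cc))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = cr + dr, cc + dc
                            if 0 <= nr < h and 0 <= nc < w and m[nr, nc] and not seen[nr, nc]:
                                seen[nr, nc] = True
                                queue.append((nr, nc))
                comps.append(comp)
    return comps


# neighbourhood in *counterclockwise* order starting east
_CCW = ((0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1))
_CW = tuple(reversed(_CCW))


def _scan(comp: set, centre, start_cell, order):
    """Scan the 8-neighbourhood of centre in the given order, starting *after*
    start_cell; return the first component pixel found, else None."""
    idx = None
    for i, (dr, dc) in enumerate(order):
        if (centre[0] + dr, centre[1] + dc) == start_cell:
            idx = i
            break
    assert idx is not None
    for k in range(1, 9):
        dr, dc = order[(idx + k) % 8]
        cand = (centre[0] + dr, centre[1] + dc)
        if cand in comp:
            return cand
    return None


def _outer_border_chain(comp: set) -> list:
    """Suzuki–Abe border following for the outer border of one component."""
    start = min(comp)  # raster order: (row, col) lexicographic
    west = (start[0], start[1] - 1)
    # step 1: clockwise scan from the west neighbour for the first pixel
    first = _scan(comp, start, west, _CW)
    if first is None:
        return [start]
    i1 = first
    i2, i3 = i1, start
    chain = [start]
    while True:
        # step 3: counterclockwise from the next cell after i2 around i3
        i4 = _scan(comp, i3, i2, _CCW)
        chain.append(i4)
        if i4 == start and i3 == i1:
            break
        i2, i3 = i3, i4
    return chain


def perimeter_oracle(mask: np.ndarray) -> float:
    """Summed closed outer-border arc length over 8-connected components."""
    total = 0.0
    for comp in _bfs_components(mask):
        chain = _outer_border_chain(comp)
        if len(chain) == 1:
            continue
        for (r0, c0), (r1, c1) in zip(chain[:-1], chain[1:]):
            total += math.hypot(r1 - r0, c1 - c0)
    return total
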