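"""Synthetic tissue-culture scenes with exact ground truth.

Renders grass-like tillers (curved, tapered quadratic-Bézier strokes fanning
out of a base point) on a deep blue background, with an optional pale medium
band across the vessel base. Foreground colour interpolates between a green
and a chlorotic-yellow endpoint under a chlorosis weight ``c`` plus bounded
uniform per-pixel jitter, so the Y-channel separation guarantee stays
provable. The ground truth records the exact painted mask, the signed Lab
table of the painted pixels, and the traits derivable from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from vitrophen import colour, verdancy
from vitrophen.errors import ConfigurationError

RGB = Tuple[int, int, int]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene; fully determines the render via ``seed``."""

    seed: int = 0
    canvas: Tuple[int, int] = (360, 480)  # (H, W)
    background_rgb: RGB = (40, 70, 160)
    medium_row: Optional[int] = 300
    medium_rgb: RGB = (226, 221, 205)
    n_tillers: int = 5
    base_point: Optional[Tuple[int, int]] = None  # (row, col); default over medium centre
    length_range: Tuple[int, int] = (140, 230)
    tiller_width: float = 9.0
    curvature_range: Tuple[float, float] = (-0.30, 0.30)
    leaf_green_rgb: RGB = (58, 138, 42)
    leaf_yellow_rgb: RGB = (198, 196, 44)
    chlorosis: float = 0.0
    colour_jitter: int = 6

    def __post_init__(self) -> None:
        h, w = self.canvas
        if h < 8 or w < 8:
            raise ConfigurationError("canvas must be at least 8×8")
        if not 0.0 <= self.chlorosis <= 1.0:
            raise ConfigurationError("chlorosis must lie in [0, 1]")
        if self.colour_jitter < 0:
            raise ConfigurationError("colour_jitter must be ≥ 0")
        if self.n_tillers < 0:
            raise ConfigurationError("n_tillers must be ≥ 0")
        for rgb in (self.background_rgb, self.medium_rgb, self.leaf_green_rgb, self.leaf_yellow_rgb):
            if any(not 0 <= v <= 255 for v in rgb):
                raise ConfigurationError(f"colour {rgb} outside [0, 255]")
        if self.medium_row is not None and not 0 <= self.medium_row < h:
            raise ConfigurationError(f"medium_row {self.medium_row} outside canvas height {h}")
        base = self._resolved_base()
        if not (0 <= base[0] < h and 0 <= base[1] < w):
            raise ConfigurationError(f"base_point {base} outside canvas {self.canvas}")
        margin = self.tiller_width / 2 + 2
        lmax = self.length_range[1]
        if base[0] - lmax - margin < 0:
            raise ConfigurationError(
                f"tillers of length up to {lmax} from base row {base[0]} exceed the canvas top"
            )
        reach = max(abs(self.curvature_range[0]), abs(self.curvature_range[1])) * lmax
        if base[1] - reach - margin < 0 or base[1] + reach + margin >= w:
            raise ConfigurationError("tiller curvature reach exceeds canvas sides")

    def _resolved_base(self) -> Tuple[int, int]:
        if self.base_point is not None:
            return self.base_point
        h, w = self.canvas
        row = self.medium_row + min(8, h - 1 - self.medium_row) if self.medium_row is not None else h - 12
        return (row, w // 2)


@dataclass(frozen=True)
class GroundTruth:
    """Exact truth for one rendered scene."""

    truth_mask: np.ndarray
    truth_pixels: np.ndarray  # (N, 3) signed Lab rows, raster order
    area: int
    area_above: Optional[int]
    area_below: Optional[int]
    greenness: Optional[float]
    spec: SceneSpec = field(repr=False, default=None)


def _stamp_disk(mask: np.ndarray, row: float, col: float, radius: float) -> None:
    h, w = mask.shape
    r0 = max(int(np.floor(row - radius)), 0)
    r1 = min(int(np.ceil(row + radius)), h - 1)
    c0 = max(int(np.floor(col - radius)), 0)
    c1 = min(int(np.ceil(col + radius)), w - 1)
    if r0 > r1 or c0 > c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    mask[r0 : r1 + 1, c0 : c1 + 1] |= (rr - row) ** 2 + (cc - col) ** 2 <= radius**2


def _render_tiller(mask: np.ndarray, base: Tuple[int, int], length: float,
                   curvature: float, width: float, lean: float) -> None:
    """Paint one tapered quadratic-Bézier stroke rising from the base point."""
    p0 = np.array([float(base[0]), float(base[1])])
    p2 = p0 + np.array([-length, (curvature + lean) * length])
    p1 = p0 + np.array([-0.55 * length, lean * 0.5 * length])
    n = max(int(3 * length), 16)
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
    radii = (width / 2.0) * (1.0 - 0.72 * t[:, 0]) + 0.6
    for (r, c), rad in zip(pts, radii):
        _stamp_disk(mask, r, c, rad)


def generate_scene(spec: SceneSpec) -> Tuple[np.ndarray, GroundTruth]:
    """Render a scene; deterministic given ``spec`` (including its seed)."""
    h, w = spec.canvas
    rng = np.random.default_rng(spec.seed)

    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = np.asarray(spec.background_rgb, dtype=np.uint8)
    if spec.medium_row is not None:
        img[spec.medium_row :] = np.asarray(spec.medium_rgb, dtype=np.uint8)

    mask = np.zeros((h, w), dtype=bool)
    base = spec._resolved_base()
    lmin, lmax = spec.length_range
    for _ in range(spec.n_tillers):
        length = rng.uniform(lmin, lmax)
        curvature = rng.uniform(*spec.curvature_range)
        lean = rng.uniform(-0.08, 0.08)
        width = spec.tiller_width * rng.uniform(0.85, 1.0)
        _render_tiller(mask, base, length, curvature, width, lean)

    n_fg = int(mask.sum())
    if n_fg:
        c = spec.chlorosis
        green = np.asarray(spec.leaf_green_rgb, dtype=np.float64)
        yellow = np.asarray(spec.leaf_yellow_rgb, dtype=np.float64)
        base_colour = (1.0 - c) * green + c * yellow
        jitter = rng.integers(-spec.colour_jitter, spec.colour_jitter + 1, size=(n_fg, 3))
        pix = np.clip(colour.round_half_away(base_colour[None, :]) + jitter, 0, 255)
        img[mask] = pix.astype(np.uint8)

    truth_pixels = verdancy.extract_lab_pixels(img, mask)
    area_above = area_below = None
    if spec.medium_row is not None:
        area_above = int(mask[: spec.medium_row].sum())
        area_below = n_fg - area_above
    greenness = None
    if n_fg:
        qual = verdancy.qualifying_pixels(truth_pixels)
        if qual.shape[0]:
            greenness = verdancy.greenness_from_table(qual).index

    truth = GroundTruth(
        truth_mask=mask,
        truth_pixels=truth_pixels,
        area=n_fg,
        area_above=area_above,
        area_below=area_below,
        greenness=greenness,
        spec=spec,
    )
    return img, truth


@dataclass(frozen=True)
class DesignRow:
    """One scene of a designed experiment."""

    treatment: str
    day: int
    chlorosis: float
    n_tillers: int
    size_scale: float
    plant_id: Optional[str] = None


def default_experiment_design(
    treatments: Sequence[str] = ("Control", "BA", "GA3", "IAA", "Kinetin", "Zeatin"),
    days: Sequence[int] = (30, 57, 86),
) -> List[DesignRow]:
    """A 6-treatment × 3-day design: chlorosis rises and size grows with day,
    tiller count varies by treatment."""
    rows: List[DesignRow] = []
    for ti, treatment in enumerate(treatments):
        for di, day in enumerate(days):
            rows.append(
                DesignRow(
                    treatment=treatment,
                    day=day,
                    chlorosis=round(0.15 + 0.25 * di + 0.02 * ti, 3),
                    n_tillers=3 + ti,
                    size_scale=0.75 + 0.25 * di,
                    plant_id=f"{treatment}_p1",
                )
            )
    return rows


def _spec_for_row(row: DesignRow, seed: int, base_spec: SceneSpec) -> SceneSpec:
    lmin, lmax = base_spec.length_range
    return replace(
        base_spec,
        seed=seed,
        chlorosis=row.chlorosis,
        n_tillers=row.n_tillers,
        length_range=(int(lmin * row.size_scale), int(lmax * row.size_scale)),
    )


def generate_experiment(
    design: Sequence[DesignRow], seed: int = 0, base_spec: SceneSpec | None = None
):
    """Render one scene per design row; per-row seed = ``seed + row index``.

    Returns ``(scenes, truth_table)`` where scenes is a list of
    ``(row, spec, image, truth)`` tuples and truth_table a pandas DataFrame
    with one row per scene (1:1, same order).
    """
    import pandas as pd

    if len(design) == 0:
        raise ConfigurationError("experiment design must be non-empty")
    if base_spec is None:
        base_spec = SceneSpec()
    scenes = []
    records = []
    for i, row in enumerate(design):
        spec = _spec_for_row(row, seed + i, base_spec)
        img, truth = generate_scene(spec)
        plant_id = row.plant_id or f"p{i:03d}"
        scenes.append((row, spec, img, truth))
        records.append(
            {
                "image": f"{row.treatment}_{plant_id}_day{row.day}.png",
                "plant_id": plant_id,
                "treatment": row.treatment,
                "day": row.day,
                "chlorosis": row.chlorosis,
                "n_tillers": row.n_tillers,
                "size_scale": row.size_scale,
                "seed": seed + i,
                "truth_area": truth.area,
                "truth_area_above": truth.area_above,
                "truth_area_below": truth.area_below,
                "truth_greenness": truth.greenness,
            }
        )
    return scenes, pd.DataFrame.from_records(records)
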