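"""Synthetic orchard scenes with exhaustively known ground truth.

The generator emulates the study system this package targets: a planar
grid orchard (rows of apple trees at 3 m x 1 m spacing), per-tree fruit
loads stratified over the canopy (top / middle / underside), a top-view
visibility model (only part of the crop shows in nadir imagery), and a
rendered georeferenced RGB raster in which every visible fruit is a red
disk with a known tight bounding box. Nothing downstream — cropping,
detection, evaluation, calibration, mapping — needs real imagery to be
tested end to end.

Default parameters reflect a measured orchard: rows of ~41 trees, 14 rows,
per-tree totals averaging ~255 fruits (range roughly 175-308), mean stratum
shares of about 27/38/35 % for top/middle/underside, and a ground sample
distance of 4.18 mm/pixel. Rendering a full field at that GSD is enormous,
so :func:`render_scene` enforces a configurable pixel budget; tests use
small layouts and/or coarser GSD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .annotations import AnnotationSet, BBox
from .geodata import GeoRaster, make_transform, world_to_pixel

__all__ = [
    "OrchardConfig",
    "TreeRecord",
    "FruitInstance",
    "SceneBundle",
    "STRATA",
    "build_layout",
    "sample_fruit_counts",
    "assign_visibility",
    "render_scene",
    "generate_scene",
    "expected_visible_fraction",
]

STRATA = ("top", "middle", "underside")

# render colors (RGB): soil background, canopy disk, fruit disk
_BACKGROUND = (120, 104, 76)
_CANOPY = (44, 108, 48)
_FRUIT = (200, 32, 28)


@dataclass(frozen=True)
class OrchardConfig:
    """Full parameterisation of a synthetic orchard scene.

    Lengths are meters in a planar projected frame; ``row_bearing_deg`` is
    the compass bearing of the row axis (0 = +y, clockwise positive);
    ``gsd_m`` is the ground sample distance of the rendered raster.
    """

    n_rows: int = 14
    trees_per_row: int = 41
    inter_row_m: float = 3.0
    intra_row_m: float = 1.0
    row_bearing_deg: float = 0.0
    origin_world: tuple[float, float] = (0.0, 0.0)
    total_count_range: tuple[int, int] = (202, 308)
    stratum_mean_fractions: tuple[float, float, float] = (0.2731, 0.3763, 0.3506)
    stratum_concentration: float = 35.0
    visibility_probs: tuple[float, float, float] = (0.9, 0.3, 0.05)
    gsd_m: float = 0.00418
    canopy_diameter_m: float = 1.0
    fruit_diameter_m: float = 0.07
    noise_sd: float = 0.0
    seed: int = 0
    crs: str = ""
    max_pixels: int = 64_000_000

    def validate(self) -> "OrchardConfig":
        if self.n_rows < 0 or self.trees_per_row < 0:
            raise ValueError("row/tree counts must be nonnegative")
        fr = np.asarray(self.stratum_mean_fractions, dtype=float)
        if fr.shape != (3,) or abs(fr.sum() - 1.0) > 1e-9 or (fr < 0).any() or (fr > 1).any():
            raise ValueError("stratum_mean_fractions must be a 3-vector in [0,1] summing to 1")
        vp = np.asarray(self.visibility_probs, dtype=float)
        if vp.shape != (3,) or (vp < 0).any() or (vp > 1).any():
            raise ValueError("visibility_probs must be three probabilities")
        lo, hi = self.total_count_range
        if lo > hi or lo < 0:
            raise ValueError("total_count_range must satisfy 0 <= min <= max")
        if self.gsd_m <= 0 or self.canopy_diameter_m <= 0 or self.fruit_diameter_m <= 0:
            raise ValueError("gsd_m, canopy_diameter_m, fruit_diameter_m must be positive")
        if self.stratum_concentration <= 0:
            raise ValueError("stratum_concentration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        return self


@dataclass
class TreeRecord:
    """One tree: identity, grid position and (once sampled) fruit load."""

    tree_id: str
    row_index: int
    position_in_row: int
    world_xy: tuple[float, float]
    count_top: int = 0
    count_middle: int = 0
    count_underside: int = 0

    @property
    def total(self) -> int:
        return self.count_top + self.count_middle + self.count_underside

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.count_top, self.count_middle, self.count_underside)


@dataclass
class FruitInstance:
    fruit_id: str
    tree_id: str
    stratum: str
    world_xy: tuple[float, float]
    radius_m: float
    visible: bool = False


@dataclass
class SceneBundle:
    """Everything a downstream stage may need, with exact ground truth."""

    raster: GeoRaster
    trees: list[TreeRecord]
    fruits: list[FruitInstance]
    truth_boxes: AnnotationSet
    tree_layer: list[dict]          # {"geometry", "properties"} features
    config: OrchardConfig

    @property
    def visible_fruits(self) -> list[FruitInstance]:
        return [f for f in self.fruits if f.visible]


def _row_axes(bearing_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors (cross-row, along-row) for a compass bearing."""
    th = math.radians(bearing_deg)
    along = np.array([math.sin(th), math.cos(th)])
    cross = np.array([math.cos(th), -math.sin(th)])
    return cross, along


def build_layout(config: OrchardConfig) -> list[TreeRecord]:
    """Place ``n_rows x trees_per_row`` trees on the rotated grid.

    Tree (i, j) sits at ``origin + i*inter_row_m*cross + j*intra_row_m*along``
    where ``cross``/``along`` are the unit axes for ``row_bearing_deg``.
    Ids are deterministic in (row, position): ``r{i:02d}t{j:02d}``.
    """
    config.validate()
    cross, along = _row_axes(config.row_bearing_deg)
    origin = np.asarray(config.origin_world, dtype=float)
    trees = []
    for i in range(config.n_rows):
        for j in range(config.trees_per_row):
            xy = origin + i * config.inter_row_m * cross + j * config.intra_row_m * along
            trees.append(TreeRecord(
                tree_id=f"r{i:02d}t{j:02d}", row_index=i, position_in_row=j,
                world_xy=(float(xy[0]), float(xy[1]))))
    return trees


def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    """Apportion ``total`` into integer parts proportional to ``fractions``
    (deterministic, sum-exact; ties go to the lower index)."""
    raw = fractions * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def sample_fruit_counts(trees: Sequence[TreeRecord], config: OrchardConfig,
                        seed: int | None = None
                        ) -> tuple[list[TreeRecord], list[FruitInstance]]:
    """Draw per-tree totals and stratified counts, and place fruits.

    Totals are uniform integers on ``total_count_range``; per-tree stratum
    fractions are Dirichlet with mean ``stratum_mean_fractions`` and
    concentration ``stratum_concentration``, converted to integers that sum
    exactly to the total by largest-remainder apportionment. Each fruit is
    placed uniformly in the canopy disk of its tree. Fully reproducible from
    the seed (``config.seed`` when none is given).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mean = np.asarray(config.stratum_mean_fractions, dtype=float)
    alpha = mean * config.stratum_concentration
    lo, hi = config.total_count_range
    out_trees: list[TreeRecord] = []
    fruits: list[FruitInstance] = []
    r_canopy = config.canopy_diameter_m / 2.0
    for tree in trees:
        total = int(rng.integers(lo, hi + 1))
        if np.all(alpha > 0):
            fractions = rng.dirichlet(alpha)
        else:  # degenerate strata with zero mean share stay exactly zero
            fractions = mean.copy()
        counts = _largest_remainder(total, fractions)
        t = replace(tree, count_top=int(counts[0]), count_middle=int(counts[1]),
                    count_underside=int(counts[2]))
        out_trees.append(t)
        cx, cy = t.world_xy
        for s_idx, stratum in enumerate(STRATA):
            for k in range(counts[s_idx]):
                # uniform position in the canopy disk
                r = r_canopy * math.sqrt(rng.uniform())
                th = rng.uniform(0.0, 2.0 * math.pi)
                fruits.append(FruitInstance(
                    fruit_id=f"{t.tree_id}:{stratum}:{k}", tree_id=t.tree_id,
                    stratum=stratum,
                    world_xy=(cx + r * math.cos(th), cy + r * math.sin(th)),
                    radius_m=config.fruit_diameter_m / 2.0))
    return out_trees, fruits


def assign_visibility(fruits: Sequence[FruitInstance], config: OrchardConfig,
                      seed: int | None = None) -> list[FruitInstance]:
    """Flag each fruit visible-from-above with its stratum's probability."""
    config.validate()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    probs = dict(zip(STRATA, config.visibility_probs))
    return [replace(f, visible=bool(rng.uniform() < probs[f.stratum]))
            for f in fruits]


def expected_visible_fraction(config: OrchardConfig) -> float:
    """Closed-form expected fraction of a tree's fruit visible from above:
    sum over strata of mean share x visibility probability."""
    return float(np.dot(config.stratum_mean_fractions, config.visibility_probs))


def _draw_disk(pixels: np.ndarray, transform, center_world, radius_m: float,
               color) -> tuple[int, int, int, int] | None:
    """Paint a filled disk (pixel-center containment) and return its tight
    pixel bbox (half-open) or None when no pixel center falls inside.

    Subpixel disks are guaranteed at least the pixel containing the center,
    so every rendered fruit has a box.
    """
    h, w = pixels.shape[:2]
    cx, cy = center_world
    col_c, row_c = world_to_pixel(transform, (cx, cy))
    px = transform[2]
    rad_px = radius_m / px
    c0 = max(int(math.floor(col_c - rad_px)) - 1, 0)
    c1 = min(int(math.ceil(col_c + rad_px)) + 1, w)
    r0 = max(int(math.floor(row_c - rad_px)) - 1, 0)
    r1 = min(int(math.ceil(row_c + rad_px)) + 1, h)
    if c0 >= c1 or r0 >= r1:
        return None
    cols = np.arange(c0, c1) + 0.5
    rows = np.arange(r0, r1) + 0.5
    d2 = (cols[None, :] - col_c) ** 2 + (rows[:, None] - row_c) ** 2
    disk = d2 <= rad_px ** 2
    if not disk.any():
        rc, cc = int(row_c), int(col_c)
        if not (0 <= rc < h and 0 <= cc < w):
            return None
        disk = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        disk[rc - r0, cc - c0] = True
    pixels[r0:r1, c0:c1][disk] = color
    rr = np.flatnonzero(disk.any(axis=1))
    cc = np.flatnonzero(disk.any(axis=0))
    return (c0 + cc[0], r0 + rr[0], c0 + cc[-1] + 1, r0 + rr[-1] + 1)


def render_scene(trees: Sequence[TreeRecord], fruits: Sequence[FruitInstance],
                 config: OrchardConfig) -> SceneBundle:
    """Rasterize the orchard: green canopy disks, red disks for every
    *visible* fruit, optional Gaussian pixel noise, and one tight truth box
    per visible fruit. The raster covers the layout plus a margin of one
    canopy radius + 0.5 m, and its affine makes world<->pixel mapping exact.

    Raises ``ValueError`` when the raster would exceed ``config.max_pixels``
    (a full 14-row field at 4.18 mm/px is deliberately out of budget).
    """
    config.validate()
    xs = [t.world_xy[0] for t in trees] or [0.0]
    ys = [t.world_xy[1] for t in trees] or [0.0]
    margin = config.canopy_diameter_m / 2.0 + 0.5
    x0, x1 = min(xs) - margin, max(xs) + margin
    y0, y1 = min(ys) - margin, max(ys) + margin
    width = max(int(math.ceil((x1 - x0) / config.gsd_m)), 1)
    height = max(int(math.ceil((y1 - y0) / config.gsd_m)), 1)
    if width * height > config.max_pixels:
        raise ValueError(
            f"scene raster {width}x{height} exceeds the pixel budget "
            f"({config.max_pixels}); coarsen gsd_m or shrink the layout")
    transform = make_transform(x0, y1, config.gsd_m)
    pixels = np.empty((height, width, 3), dtype=np.uint8)
    pixels[:] = _BACKGROUND

    for tree in trees:
        _draw_disk(pixels, transform, tree.world_xy,
                   config.canopy_diameter_m / 2.0, _CANOPY)
    boxes = []
    for fruit in fruits:
        if not fruit.visible:
            continue
        bbox = _draw_disk(pixels, transform, fruit.world_xy, fruit.radius_m,
                          _FRUIT)
        if bbox is None:
            raise ValueError(f"visible fruit {fruit.fruit_id} fell outside the raster")
        boxes.append(BBox(*[float(v) for v in bbox]))

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed + 2)
        noisy = pixels.astype(np.float64) + rng.normal(0.0, config.noise_sd,
                                                       pixels.shape)
        pixels = np.clip(np.floor(noisy + 0.5), 0, 255).astype(np.uint8)

    truth = AnnotationSet("scene", width, height, boxes).validate()
    from shapely.geometry import Point  # local: geometry only needed here
    tree_layer = [
        {"geometry": Point(*t.world_xy),
         "properties": {"tree_id": t.tree_id, "row_index": t.row_index,
                        "position_in_row": t.position_in_row}}
        for t in trees
    ]
    raster = GeoRaster(pixels, transform, config.crs)
    return SceneBundle(raster=raster, trees=list(trees), fruits=list(fruits),
                       truth_boxes=truth, tree_layer=tree_layer, config=config)


def generate_scene(config: OrchardConfig, seed: int | None = None) -> SceneBundle:
    """Convenience: layout -> counts -> visibility -> render, one seed."""
    seed = config.seed if seed is None else seed
    trees = build_layout(config)
    trees, fruits = sample_fruit_counts(trees, config, seed)
    fruits = assign_visibility(fruits, config, seed)
    return render_scene(trees, fruits, config)
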