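"""Georeferenced raster/vector handling: affine world<->pixel transforms,
circular tree masks, and per-tree raster cropping.

Conventions
-----------
* Rasters are north-up: world x grows with pixel column, world y *decreases*
  with pixel row. The affine transform is stored as a 6-tuple
  ``(origin_x, origin_y, pixel_width_m, pixel_height_m, 0.0, 0.0)`` where the
  origin is the *outer corner* of the top-left pixel and both pixel sizes are
  positive magnitudes. Rotation/shear terms are fixed at zero.
* Pixel coordinates are 0-based and continuous: ``(0.0, 0.0)`` is the outer
  corner of the top-left pixel, so pixel centers sit at half-integer
  coordinates. Pixel windows are half-open ``[c0, c1) x [r0, r1)``.
* A pixel belongs to a circle iff the world distance from its *center* to the
  circle center is <= radius (the common zonal-statistics rule).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from shapely.geometry import mapping as shapely_mapping, shape as shapely_shape

from . import esri_shapefile

__all__ = [
    "Affine",
    "GeoRaster",
    "TreeTile",
    "pixel_to_world",
    "world_to_pixel",
    "circular_mask",
    "crop_tree_tile",
    "read_raster",
    "write_raster",
    "read_vector",
    "write_vector",
]

#: affine 6-tuple alias: (origin_x, origin_y, pixel_width_m, pixel_height_m, 0, 0)
Affine = tuple


def make_transform(origin_x: float, origin_y: float, pixel_width_m: float,
                   pixel_height_m: float | None = None) -> Affine:
    """Build a north-up affine 6-tuple; square pixels if height omitted."""
    if pixel_height_m is None:
        pixel_height_m = pixel_width_m
    if pixel_width_m <= 0 or pixel_height_m <= 0:
        raise ValueError("pixel sizes must be positive")
    return (float(origin_x), float(origin_y),
            float(pixel_width_m), float(pixel_height_m), 0.0, 0.0)


@dataclass
class GeoRaster:
    """8-bit image grid bound to world coordinates by a north-up affine."""

    pixels: np.ndarray          # (H, W, C) or (H, W), uint8
    transform: Affine
    crs: str = ""               # opaque tag, carried through I/O untouched

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be a HxW or HxWxC grid")
        if self.height < 1 or self.width < 1:
            raise ValueError("raster must be at least 1x1")
        if len(self.transform) == 4:
            self.transform = tuple(self.transform) + (0.0, 0.0)
        if self.transform[2] <= 0 or self.transform[3] <= 0:
            raise ValueError("pixel sizes must be positive magnitudes")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]


@dataclass
class TreeTile:
    """A per-tree crop of the parent raster, masked to the tree circle."""

    tree_id: str
    raster: GeoRaster
    mask: np.ndarray                 # boolean, same HxW as raster
    window_offset: tuple[int, int]   # (col, row) of tile origin in parent


def pixel_to_world(transform: Affine, col_row) -> np.ndarray:
    """Map continuous pixel coordinates ``(col, row)`` to world ``(x, y)``."""
    ox, oy, pw, ph = transform[:4]
    cr = np.asarray(col_row, dtype=float)
    col, row = cr[..., 0], cr[..., 1]
    return np.stack([ox + col * pw, oy - row * ph], axis=-1)


def world_to_pixel(transform: Affine, xy_world) -> np.ndarray:
    """Map world ``(x, y)`` to continuous pixel coordinates ``(col, row)``.

    Exact inverse of :func:`pixel_to_world`; out-of-bounds coordinates are
    returned as-is (the caller clips).
    """
    ox, oy, pw, ph = transform[:4]
    xy = np.asarray(xy_world, dtype=float)
    x, y = xy[..., 0], xy[..., 1]
    return np.stack([(x - ox) / pw, (oy - y) / ph], axis=-1)


def _pixel_center_grid(transform: Affine, rows: np.ndarray, cols: np.ndarray):
    """World coordinates of pixel centers for given row/col index vectors."""
    ox, oy, pw, ph = transform[:4]
    xs = ox + (cols + 0.5) * pw
    ys = oy - (rows + 0.5) * ph
    return xs, ys


def circular_mask(raster: GeoRaster, center_world, diameter_m: float) -> np.ndarray:
    """Boolean H x W mask of pixels whose centers lie within the circle.

    Warns (``UserWarning``) and returns an all-false mask when the circle
    misses the raster entirely.
    """
    if diameter_m <= 0:
        raise ValueError("diameter_m must be positive")
    cx, cy = float(center_world[0]), float(center_world[1])
    rows = np.arange(raster.height, dtype=float)
    cols = np.arange(raster.width, dtype=float)
    xs, ys = _pixel_center_grid(raster.transform, rows, cols)
    d2 = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2
    mask = d2 <= (diameter_m / 2.0) ** 2
    if not mask.any():
        warnings.warn(
            f"circle at ({cx:.3f}, {cy:.3f}) d={diameter_m} m covers no pixel "
            "center of the raster", UserWarning, stacklevel=2)
    return mask


def crop_tree_tile(raster: GeoRaster, tree, diameter_m: float) -> TreeTile:
    """Crop the tight window of a 1-tree circle and black out pixels outside it.

    ``tree`` needs ``tree_id`` and ``world_xy`` attributes (a
    :class:`~orchardyield.synthetic.TreeRecord` works). The tile keeps its
    georeference: its transform is the parent transform shifted by the window
    offset. Raises ``ValueError`` naming the tree when the circle misses the
    raster.
    """
    if diameter_m <= 0:
        raise ValueError("diameter_m must be positive")
    cx, cy = float(tree.world_xy[0]), float(tree.world_xy[1])
    r = diameter_m / 2.0
    # continuous pixel extent of the circle, clipped to the raster
    (c0f, r0f) = world_to_pixel(raster.transform, (cx - r, cy + r))
    (c1f, r1f) = world_to_pixel(raster.transform, (cx + r, cy - r))
    c0 = max(int(np.floor(c0f)), 0)
    r0 = max(int(np.floor(r0f)), 0)
    c1 = min(int(np.ceil(c1f)), raster.width)
    r1 = min(int(np.ceil(r1f)), raster.height)
    if c0 >= c1 or r0 >= r1:
        raise ValueError(f"tree {tree.tree_id!r}: circle does not intersect the raster")

    rows = np.arange(r0, r1, dtype=float)
    cols = np.arange(c0, c1, dtype=float)
    xs, ys = _pixel_center_grid(raster.transform, rows, cols)
    mask = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2 <= r * r
    if not mask.any():
        raise ValueError(f"tree {tree.tree_id!r}: circle covers no pixel center")

    # tighten window to rows/cols with at least one masked pixel
    rr = np.flatnonzero(mask.any(axis=1))
    cc = np.flatnonzero(mask.any(axis=0))
    tr0, tr1 = rr[0], rr[-1] + 1
    tc0, tc1 = cc[0], cc[-1] + 1
    mask = mask[tr0:tr1, tc0:tc1]
    r0, r1 = r0 + tr0, r0 + tr1
    c0, c1 = c0 + tc0, c0 + tc1

    tile_pixels = raster.pixels[r0:r1, c0:c1].copy()
    tile_pixels[~mask] = 0
    ox, oy, pw, ph = raster.transform[:4]
    tile_transform = make_transform(ox + c0 * pw, oy - r0 * ph, pw, ph)
    tile = GeoRaster(tile_pixels, tile_transform, raster.crs)
    return TreeTile(tree_id=str(tree.tree_id), raster=tile, mask=mask,
                    window_offset=(int(c0), int(r0)))


# ---------------------------------------------------------------------------
# raster I/O (GeoTIFF via the standard ModelPixelScale/ModelTiepoint tags)
# ---------------------------------------------------------------------------

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922


def write_raster(raster: GeoRaster, path) -> None:
    """Write an 8-bit GeoTIFF carrying pixel scale, tiepoint and CRS tag."""
    path = Path(path)
    if path.suffix.lower() not in {".tif", ".tiff"}:
        raise ValueError(f"unknown raster extension: {path.suffix!r}")
    ox, oy, pw, ph = raster.transform[:4]
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (pw, ph, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0)),
    ]
    pixels = raster.pixels
    photometric = "rgb" if pixels.shape[2] >= 3 else "minisblack"
    if pixels.shape[2] == 1:
        pixels = pixels[:, :, 0]
    tifffile.imwrite(path, pixels, photometric=photometric,
                     description=json.dumps({"crs": raster.crs}),
                     extratags=extratags)


def read_raster(path) -> GeoRaster:
    """Read a GeoTIFF written by :func:`write_raster` (or any north-up
    GeoTIFF carrying ModelPixelScale + ModelTiepoint tags)."""
    path = Path(path)
    if path.suffix.lower() not in {".tif", ".tiff"}:
        raise ValueError(f"unknown raster extension: {path.suffix!r}")
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            pixels = page.asarray()
            tags = page.tags
            if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
                raise ValueError(f"{path}: missing GeoTIFF georeference tags")
            pw, ph = tags[_TAG_PIXEL_SCALE].value[:2]
            tie = tags[_TAG_TIEPOINT].value
            i, j = tie[0], tie[1]
            x, y = tie[3], tie[4]
            ox, oy = x - i * pw, y + j * ph
            crs = ""
            desc = tags.get("ImageDescription")
            if desc is not None:
                try:
                    crs = json.loads(desc.value).get("crs", "")
                except (json.JSONDecodeError, AttributeError, TypeError):
                    pass
    except tifffile.TiffFileError as exc:
        raise ValueError(f"{path}: not a readable TIFF ({exc})") from exc
    return GeoRaster(pixels, make_transform(ox, oy, pw, ph), crs)


# ---------------------------------------------------------------------------
# vector I/O (GeoJSON and ESRI Shapefile)
# ---------------------------------------------------------------------------

def write_vector(features: Sequence[dict], path, crs: str = "") -> dict:
    """Write point/line/polygon features with attributes.

    ``features`` is a list of ``{"geometry": <shapely geometry>,
    "properties": {name: value}}`` mappings. Format is chosen by extension:
    ``.geojson``/``.json`` or ``.shp``. Returns the attribute renaming map
    (original -> written name); it is the identity except for the Shapefile
    10-character field-name truncation.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext in {".geojson", ".json"}:
        fc = {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature",
                 "geometry": shapely_mapping(f["geometry"]),
                 "properties": dict(f["properties"])}
                for f in features
            ],
        }
        if crs:
            fc["crs"] = {"type": "name", "properties": {"name": crs}}
        path.write_text(json.dumps(fc, indent=1))
        names = set()
        for f in features:
            names.update(f["properties"])
        return {n: n for n in sorted(names)}
    if ext == ".shp":
        return esri_shapefile.write(features, path, crs=crs)
    raise ValueError(f"unknown vector extension: {ext!r}")


def read_vector(path) -> list[dict]:
    """Read features written by :func:`write_vector` back as shapely-backed
    ``{"geometry", "properties"}`` mappings."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext in {".geojson", ".json"}:
        try:
            fc = json.loads(path.read_text())
            return [
                {"geometry": shapely_shape(f["geometry"]),
                 "properties": dict(f["properties"])}
                for f in fc["features"]
            ]
        except (json.JSONDecodeError, KeyError) as exc:
            raise ValueError(f"{path}: malformed GeoJSON ({exc})") from exc
    if ext == ".shp":
        return esri_shapefile.read(path)
    raise ValueError(f"unknown vector extension: {ext!r}")
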