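"""Fruit detection: a pluggable detector contract, a deterministic classical
reference detector (HSV color-blob analysis with non-maximum suppression),
and per-tree counting over circular canopy crops.

The detector contract is intentionally minimal — any callable mapping an RGB
tile to a :class:`DetectionSet` plugs into :func:`count_per_tree` — so a
learned detector can replace the reference implementation without touching
the surrounding pipeline. The reference detector's score is the component's
circularity ``4*pi*A / P**2`` capped at 1: a bounded, deterministic proxy for
"fruit-likeness" of rendered disks, not a calibrated probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from skimage import color as skcolor
from skimage import measure as skmeasure

from .annotations import BBox
from .geodata import GeoRaster, crop_tree_tile

__all__ = [
    "DetectorParams",
    "DetectionSet",
    "Detector",
    "reference_blob_detect",
    "make_reference_detector",
    "nms",
    "count_per_tree",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectorParams:
    """Reference-detector thresholds.

    ``hue_window`` is an angular interval in degrees on the color wheel
    (wrap-around allowed, e.g. ``(335, 25)`` selects red); saturation/value
    cutoffs are in [0, 1]; ``area_range_px`` bounds component pixel area;
    ``min_circularity`` filters ragged components; ``nms_iou`` is the
    suppression threshold; ``score_floor`` the counting threshold.
    """

    hue_window: tuple[float, float] = (335.0, 25.0)
    min_saturation: float = 0.35
    min_value: float = 0.15
    area_range_px: tuple[float, float] = (4.0, 1e6)
    min_circularity: float = 0.3
    nms_iou: float = 0.5
    score_floor: float = 0.5

    def __post_init__(self):
        if self.area_range_px[0] > self.area_range_px[1]:
            raise ValueError("area_range_px must be ordered")
        for name in ("min_saturation", "min_value", "min_circularity",
                     "nms_iou", "score_floor"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class DetectionSet:
    """Scored boxes for one image, sorted by descending score
    (ties broken by (ymin, xmin))."""

    image_id: str
    boxes: list[BBox] = field(default_factory=list)

    def sorted(self) -> "DetectionSet":
        ordered = sorted(self.boxes,
                         key=lambda b: (-(b.score or 0.0), b.ymin, b.xmin))
        return DetectionSet(self.image_id, ordered)

    def count(self, score_floor: float = 0.0) -> int:
        return sum(1 for b in self.boxes if (b.score or 0.0) >= score_floor)


class Detector(Protocol):
    """Contract: RGB tile (H, W, 3) uint8 -> DetectionSet, deterministic for
    a deterministic implementation."""

    def __call__(self, tile: np.ndarray, image_id: str = "") -> DetectionSet: ...


def _hue_mask(hue_deg: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window[0] % 360.0, window[1] % 360.0
    if lo <= hi:
        return (hue_deg >= lo) & (hue_deg <= hi)
    return (hue_deg >= lo) | (hue_deg <= hi)


def reference_blob_detect(tile: np.ndarray, params: DetectorParams | None = None,
                          image_id: str = "") -> DetectionSet:
    """Deterministic classical detector for red fruit blobs.

    Pipeline: RGB -> HSV; threshold on hue window, saturation and value;
    8-connected components; discard components outside ``area_range_px`` or
    below ``min_circularity``; per survivor emit its tight bbox scored by
    circularity (capped at 1); finally greedy NMS at ``nms_iou``.
    """
    params = params or DetectorParams()
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[2] < 3:
        raise ValueError("detector expects an RGB tile (H, W, 3)")
    hsv = skcolor.rgb2hsv(tile[:, :, :3])
    hue_deg = hsv[:, :, 0] * 360.0
    mask = (_hue_mask(hue_deg, params.hue_window)
            & (hsv[:, :, 1] >= params.min_saturation)
            & (hsv[:, :, 2] >= params.min_value))
    labels = skmeasure.label(mask, connectivity=2)
    boxes = []
    for region in skmeasure.regionprops(labels):
        area = float(region.area)
        if not (params.area_range_px[0] <= area <= params.area_range_px[1]):
            continue
        perimeter = float(region.perimeter)
        circularity = 1.0 if perimeter == 0 else 4.0 * np.pi * area / perimeter ** 2
        if circularity < params.min_circularity:
            continue
        r0, c0, r1, c1 = region.bbox
        boxes.append(BBox(float(c0), float(r0), float(c1), float(r1),
                          score=min(1.0, circularity)))
    detections = DetectionSet(image_id, boxes).sorted()
    return DetectionSet(image_id, nms(detections.boxes, params.nms_iou))


def make_reference_detector(params: DetectorParams | None = None) -> Detector:
    """Bind parameters into a detector satisfying the contract."""
    params = params or DetectorParams()

    def _detector(tile: np.ndarray, image_id: str = "") -> DetectionSet:
        return reference_blob_detect(tile, params, image_id)

    return _detector


def nms(boxes: Sequence[BBox], iou_thresh: float) -> list[BBox]:
    """Greedy non-maximum suppression.

    Boxes are visited in descending score order (ties by (ymin, xmin)); a box
    is suppressed iff its IoU with an already-kept box exceeds
    ``iou_thresh``.
    """
    from .evaluation import iou  # late import: evaluation depends on nothing here
    ordered = sorted(boxes, key=lambda b: (-(b.score or 0.0), b.ymin, b.xmin))
    kept: list[BBox] = []
    for box in ordered:
        if all(iou(box, k) <= iou_thresh for k in kept):
            kept.append(box)
    return kept


def count_per_tree(raster: GeoRaster, trees: Sequence, detector: Detector,
                   diameter_m: float = 1.0, score_floor: float = 0.5
                   ) -> tuple[dict[str, int | None], dict[str, DetectionSet]]:
    """Detect and count fruits per tree over circular canopy crops.

    Each tree is cropped with :func:`~orchardyield.geodata.crop_tree_tile`,
    run through ``detector``, and its boxes with score >= ``score_floor``
    counted. A tree whose crop fails (e.g. it misses the raster) is logged
    and reported with count ``None`` instead of aborting the batch.

    Returns ``(counts, detections)`` keyed by tree_id; detection boxes are in
    tile-local pixel coordinates (the tile's ``window_offset`` places them in
    the parent raster).
    """
    counts: dict[str, int | None] = {}
    detections: dict[str, DetectionSet] = {}
    for tree in trees:
        try:
            tile = crop_tree_tile(raster, tree, diameter_m)
        except ValueError as exc:
            logger.warning("skipping tree %s: %s", tree.tree_id, exc)
            counts[str(tree.tree_id)] = None
            continue
        dets = detector(tile.raster.pixels, image_id=str(tree.tree_id))
        detections[str(tree.tree_id)] = dets
        counts[str(tree.tree_id)] = dets.count(score_floor)
    return counts, detections
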