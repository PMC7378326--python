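"""PASCAL VOC annotation handling, fixed-grid image tiling and the
augmentations used to grow a fruit-detection training set (right-angle
rotations and linear brightness/contrast shifts).

Internally every bounding box is 0-based and half-open,
``[xmin, xmax) x [ymin, ymax)`` in pixel coordinates. The VOC XML dialect is
1-based with inclusive maxima; conversion happens only at the I/O boundary,
so an internal box ``(0, 0, 10, 10)`` is written as ``bndbox`` 1,1,10,10.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from lxml import etree

__all__ = [
    "BBox",
    "AnnotationSet",
    "AugmentParams",
    "read_voc",
    "write_voc",
    "tile_image",
    "rotate",
    "brightness_contrast",
    "augment_dataset",
]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box, 0-based half-open pixel coordinates."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    label: str = "apple"
    score: float | None = None

    def __post_init__(self):
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(f"degenerate box {(self.xmin, self.ymin, self.xmax, self.ymax)}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    def clip(self, xmin: float, ymin: float, xmax: float, ymax: float) -> "BBox | None":
        """Intersect with a window; None when the intersection is empty."""
        x0, y0 = max(self.xmin, xmin), max(self.ymin, ymin)
        x1, y1 = min(self.xmax, xmax), min(self.ymax, ymax)
        if x1 <= x0 or y1 <= y0:
            return None
        return replace(self, xmin=x0, ymin=y0, xmax=x1, ymax=y1)

    def shift(self, dx: float, dy: float) -> "BBox":
        return replace(self, xmin=self.xmin + dx, ymin=self.ymin + dy,
                       xmax=self.xmax + dx, ymax=self.ymax + dy)


@dataclass
class AnnotationSet:
    """All boxes of one image."""

    image_id: str
    width: int
    height: int
    boxes: list[BBox] = field(default_factory=list)

    def validate(self) -> "AnnotationSet":
        for b in self.boxes:
            if b.xmin < 0 or b.ymin < 0 or b.xmax > self.width or b.ymax > self.height:
                raise ValueError(f"{self.image_id}: box {b} outside {self.width}x{self.height}")
        return self


@dataclass(frozen=True)
class AugmentParams:
    """Deterministic augmentation recipe: right-angle rotations plus one
    linear intensity map ``out = alpha * in + beta`` (identity by default)."""

    rotations: tuple[int, ...] = ()
    alpha: float = 1.0
    beta: float = 0.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        bad = set(self.rotations) - {90, 180, 270}
        if bad:
            raise ValueError(f"unsupported rotation angles: {sorted(bad)}")

    @property
    def expansion_factor(self) -> int:
        color = 1 if (self.alpha != 1.0 or self.beta != 0.0) else 0
        return 1 + len(self.rotations) + color


# ---------------------------------------------------------------------------
# PASCAL VOC XML
# ---------------------------------------------------------------------------

def _req(parent, tag, path):
    node = parent.find(tag)
    if node is None:
        raise ValueError(f"{path}: missing <{tag}> element")
    return node


def read_voc(path) -> AnnotationSet:
    """Parse a VOC XML file into an :class:`AnnotationSet` (0-based boxes)."""
    path = Path(path)
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"{path}: malformed XML ({exc})") from exc
    size = _req(root, "size", path)
    width = int(_req(size, "width", path).text)
    height = int(_req(size, "height", path).text)
    fname = root.findtext("filename", default=path.stem)
    boxes = []
    for obj in root.iter("object"):
        label = obj.findtext("name", default="apple")
        bnd = _req(obj, "bndbox", path)
        xmin = float(_req(bnd, "xmin", path).text) - 1
        ymin = float(_req(bnd, "ymin", path).text) - 1
        xmax = float(_req(bnd, "xmax", path).text)
        ymax = float(_req(bnd, "ymax", path).text)
        score_text = obj.findtext("score")
        score = float(score_text) if score_text is not None else None
        boxes.append(BBox(xmin, ymin, xmax, ymax, label=label, score=score))
    return AnnotationSet(image_id=fname, width=width, height=height,
                         boxes=boxes).validate()


def write_voc(annotations: AnnotationSet, path) -> None:
    """Write VOC XML (1-based inclusive bndbox; detector scores, when
    present, go in a non-standard ``score`` element)."""
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = "images"
    etree.SubElement(root, "filename").text = annotations.image_id
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(annotations.width)
    etree.SubElement(size, "height").text = str(annotations.height)
    etree.SubElement(size, "depth").text = "3"
    for b in annotations.boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = b.label
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(int(round(b.xmin)) + 1)
        etree.SubElement(bnd, "ymin").text = str(int(round(b.ymin)) + 1)
        etree.SubElement(bnd, "xmax").text = str(int(round(b.xmax)))
        etree.SubElement(bnd, "ymax").text = str(int(round(b.ymax)))
        if b.score is not None:
            etree.SubElement(obj, "score").text = repr(b.score)
    Path(path).write_bytes(etree.tostring(root, pretty_print=True,
                                          xml_declaration=False))


# ---------------------------------------------------------------------------
# tiling and augmentation
# ---------------------------------------------------------------------------

def tile_image(image: np.ndarray, annotations: AnnotationSet,
               tile_size: int = 416, min_visibility: float = 0.25
               ) -> list[tuple[np.ndarray, AnnotationSet]]:
    """Cut an image into non-overlapping ``tile_size`` tiles on a regular
    grid. Remainder tiles at the right/bottom edges keep their native size
    (no resizing). A box is copied into every tile it intersects, clipped to
    the tile; clipped copies keeping less than ``min_visibility`` of the
    original area are dropped.
    """
    h, w = image.shape[:2]
    if h < 1 or w < 1:
        raise ValueError("image must be at least 1x1")
    tiles = []
    for y0 in range(0, h, tile_size):
        for x0 in range(0, w, tile_size):
            x1, y1 = min(x0 + tile_size, w), min(y0 + tile_size, h)
            boxes = []
            for box in annotations.boxes:
                clipped = box.clip(x0, y0, x1, y1)
                if clipped is None:
                    continue
                if clipped.area < min_visibility * box.area:
                    continue
                boxes.append(clipped.shift(-x0, -y0))
            tile_id = f"{annotations.image_id}_x{x0}_y{y0}"
            tiles.append((image[y0:y1, x0:x1].copy(),
                          AnnotationSet(tile_id, x1 - x0, y1 - y0, boxes).validate()))
    return tiles


def _rotate90_box(box: BBox, w: int, h: int) -> BBox:
    # 90 deg clockwise: pixel (x, y) of a WxH image -> (H-1-y, x)
    return replace(box, xmin=h - box.ymax, ymin=box.xmin,
                   xmax=h - box.ymin, ymax=box.xmax)


def rotate(image: np.ndarray, annotations: AnnotationSet, angle: int
           ) -> tuple[np.ndarray, AnnotationSet]:
    """Rotate image + boxes by 90/180/270 degrees clockwise."""
    if angle not in (90, 180, 270):
        raise ValueError(f"angle must be one of 90, 180, 270 (got {angle})")
    out_img, boxes = image, list(annotations.boxes)
    w, h = annotations.width, annotations.height
    for _ in range(angle // 90):
        out_img = np.rot90(out_img, k=-1).copy()
        boxes = [_rotate90_box(b, w, h) for b in boxes]
        w, h = h, w
    return out_img, AnnotationSet(f"{annotations.image_id}_rot{angle}",
                                  w, h, boxes).validate()


def brightness_contrast(image: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Linear intensity map ``clip(round(alpha * in + beta), 0, 255)`` applied
    uniformly to all channels. Boxes are unaffected by this transform."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    out = np.floor(alpha * image.astype(np.float64) + beta + 0.5)
    return np.clip(out, 0, 255).astype(np.uint8)


def augment_dataset(dataset: Sequence[tuple[np.ndarray, AnnotationSet]],
                    params: AugmentParams
                    ) -> list[tuple[np.ndarray, AnnotationSet]]:
    """Deterministically expand a dataset: every original image, then its
    rotated copies, then (if the intensity map is not the identity) its
    brightness/contrast variant. Output size = ``params.expansion_factor``
    times the input size."""
    out: list[tuple[np.ndarray, AnnotationSet]] = []
    color = params.alpha != 1.0 or params.beta != 0.0
    for image, ann in dataset:
        out.append((image, ann))
        for angle in params.rotations:
            out.append(rotate(image, ann, angle))
        if color:
            aug = brightness_contrast(image, params.alpha, params.beta)
            out.append((aug, replace_id(ann, f"{ann.image_id}_a{params.alpha}_b{params.beta}")))
    return out


def replace_id(annotations: AnnotationSet, new_id: str) -> AnnotationSet:
    return AnnotationSet(new_id, annotations.width, annotations.height,
                         list(annotations.boxes))
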