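"""Shared fixtures: small synthetic scenes and independent oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from shapely.geometry import box as shapely_box

from orchardyield.annotations import BBox
from orchardyield.synthetic import (FruitInstance, OrchardConfig, build_layout,
                                    render_scene)


@pytest.fixture(scope="session")
def small_config() -> OrchardConfig:
    """3x5-tree orchard at 1 cm GSD — renders in well under a second."""
    return OrchardConfig(n_rows=3, trees_per_row=5, gsd_m=0.01,
                         total_count_range=(20, 30), seed=42)


def place_grid_fruits(trees, config, per_tree, spacing_m=0.2):
    """Deterministic, non-overlapping fruit placement: a small grid inside
    each canopy disk; all fruits marked visible. Independent of the
    generator's random placement, so clean-scene tests have exact truth."""
    fruits = []
    for tree in trees:
        cx, cy = tree.world_xy
        offsets = [(i * spacing_m, j * spacing_m)
                   for i in (-1, 0, 1) for j in (-1, 0, 1)]
        assert per_tree <= len(offsets)
        for k in range(per_tree):
            dx, dy = offsets[k]
            fruits.append(FruitInstance(
                fruit_id=f"{tree.tree_id}:f{k}", tree_id=tree.tree_id,
                stratum="top", world_xy=(cx + dx, cy + dy),
                radius_m=config.fruit_diameter_m / 2.0, visible=True))
    return fruits


@pytest.fixture(scope="session")
def clean_scene(small_config):
    """Noise-free scene with known non-overlapping fruits (3 per tree)."""
    trees = build_layout(small_config)
    fruits = place_grid_fruits(trees, small_config, per_tree=3)
    return render_scene(trees, fruits, small_config)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def shapely_iou(a: BBox, b: BBox) -> float:
    """IoU via shapely polygon ops — an independent geometric route."""
    pa = shapely_box(a.xmin, a.ymin, a.xmax, a.ymax)
    pb = shapely_box(b.xmin, b.ymin, b.xmax, b.ymax)
    inter = pa.intersection(pb).area
    union = pa.union(pb).area
    return inter / union if union > 0 else 0.0


def brute_force_nms(boxes, iou_thresh):
    """Quadratic reference NMS using the shapely IoU route."""
    ordered = sorted(boxes, key=lambda b: (-(b.score or 0.0), b.ymin, b.xmin))
    kept = []
    for box in ordered:
        if all(shapely_iou(box, k) <= iou_thresh for k in kept):
            kept.append(box)
    return kept


def optimal_match_count(detections, truth, iou_min=0.5) -> int:
    """Exhaustive maximum one-to-one matching (feasible for <= 6 boxes):
    the largest number of detection/truth pairs with IoU >= iou_min."""
    n_det, n_tru = len(detections), len(truth)
    feasible = {(i, j) for i in range(n_det) for j in range(n_tru)
                if shapely_iou(detections[i], truth[j]) >= iou_min}
    best = 0
    for k in range(min(n_det, n_tru), 0, -1):
        for det_subset in itertools.combinations(range(n_det), k):
            for tru_perm in itertools.permutations(range(n_tru), k):
                if all((d, t) in feasible
                       for d, t in zip(det_subset, tru_perm)):
                    return k
    return best


def random_boxes(rng: np.random.Generator, n: int, extent: int = 50,
                 scored: bool = True) -> list[BBox]:
    boxes = []
    for _ in range(n):
        x0 = rng.uniform(0, extent - 2)
        y0 = rng.uniform(0, extent - 2)
        boxes.append(BBox(x0, y0, x0 + rng.uniform(1, 10), y0 + rng.uniform(1, 10),
                          score=float(rng.uniform()) if scored else None))
    return boxes
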