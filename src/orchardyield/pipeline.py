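"""Configuration-driven orchestration of the full analysis:
simulate -> crop+detect -> evaluate -> calibrate -> map.

Every stage persists its outputs under ``RunConfig.output_dir`` and can be
re-run from the files a previous stage left behind; a :class:`RunManifest`
records the configuration snapshot, per-stage record counts and timings.
Identical (config, seed) runs produce byte-identical data files (timings
excluded, which is why they live only in the manifest).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations import BBox, read_voc, write_voc
from .detection import DetectorParams, make_reference_detector
from .evaluation import (detection_metrics, match_detections, metrics_table,
                         round_half_up)
from .geodata import read_raster, read_vector, write_raster, write_vector, world_to_pixel
from .synthetic import OrchardConfig, TreeRecord, generate_scene
from .yield_estimation import CalibrationPair, fit_calibration, predict_total
from .yield_map import DEFAULT_BIN_EDGES, per_row_layer, per_tree_layer

__all__ = ["RunConfig", "RunManifest", "cmd_simulate", "cmd_detect",
           "cmd_evaluate", "cmd_calibrate", "cmd_map", "cmd_run_all"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from a YAML file."""

    output_dir: Path = Path("orchardyield_run")
    orchard: OrchardConfig = field(default_factory=OrchardConfig)
    detector: DetectorParams = field(default_factory=DetectorParams)
    diameter_m: float = 1.0          # circular mask diameter per tree
    iou_min: float = 0.5             # TP matching threshold
    score_floor: float = 0.5         # detection counting threshold
    bin_edges: tuple = DEFAULT_BIN_EDGES
    seed: int = 0
    # optional external inputs; default to the simulate stage's outputs
    raster_path: Path | None = None
    tree_layer_path: Path | None = None
    truth_voc_path: Path | None = None
    calibration_csv: Path | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "orchard" in raw:
            kwargs["orchard"] = OrchardConfig(**raw.pop("orchard"))
        if "detector" in raw:
            kwargs["detector"] = DetectorParams(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw.pop("detector").items()})
        for key in ("output_dir", "raster_path", "tree_layer_path",
                    "truth_voc_path", "calibration_csv"):
            if raw.get(key) is not None:
                kwargs[key] = Path(raw.pop(key))
            else:
                raw.pop(key, None)
        if "bin_edges" in raw:
            kwargs["bin_edges"] = tuple(raw.pop("bin_edges"))
        kwargs.update(raw)
        return cls(**kwargs)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=str))

    def _default(self, attr: str, filename: str) -> Path:
        explicit = getattr(self, attr)
        return Path(explicit) if explicit else self.output_dir / filename


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    seed: int = 0
    stages: dict = field(default_factory=dict)   # name -> {records, seconds}

    def record(self, name: str, n_records: int, seconds: float) -> None:
        if name in self.stages:
            raise ValueError(f"stage {name!r} recorded twice")
        self.stages[name] = {"records": int(n_records),
                             "seconds": round(seconds, 3)}

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"version": self.version, "seed": self.seed,
             "stages": self.stages, "config": self.config}, indent=1))


def _stage(manifest: RunManifest | None, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("=== stage %s ===", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc_type is not None:
                logger.error("stage %s failed: %s", name, exc)
                return False
            if manifest is not None:
                manifest.record(name, self.records, time.perf_counter() - self.t0)
            logger.info("stage %s done (%d records)", name, self.records)
            return False

        records = 0
    return _Timer()


def cmd_simulate(config: RunConfig, manifest: RunManifest | None = None):
    """Generate a synthetic scene and persist raster, tree layer, truth
    boxes (VOC) and the per-tree truth table (CSV)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with _stage(manifest, "simulate") as st:
        orchard = dataclasses.replace(config.orchard, seed=config.seed)
        scene = generate_scene(orchard)
        write_raster(scene.raster, out / "scene.tif")
        write_vector(scene.tree_layer, out / "trees.geojson", crs=orchard.crs)
        write_vector(scene.tree_layer, out / "trees.shp", crs=orchard.crs)
        write_voc(scene.truth_boxes, out / "truth_boxes.xml")
        visible = {}
        for f in scene.fruits:
            if f.visible:
                visible[f.tree_id] = visible.get(f.tree_id, 0) + 1
        rows = [{"tree_id": t.tree_id, "row_index": t.row_index,
                 "position_in_row": t.position_in_row,
                 "count_top": t.count_top, "count_middle": t.count_middle,
                 "count_underside": t.count_underside, "total": t.total,
                 "n_visible": visible.get(t.tree_id, 0)}
                for t in scene.trees]
        pd.DataFrame(rows).to_csv(out / "truth_trees.csv", index=False)
        st.records = len(scene.trees)
    return scene


def _load_trees(config: RunConfig) -> list[TreeRecord]:
    path = config._default("tree_layer_path", "trees.geojson")
    if not path.exists():
        raise FileNotFoundError(f"tree layer not found: {path} "
                                "(run the simulate stage or set tree_layer_path)")
    trees = []
    for feat in read_vector(path):
        p = feat["properties"]
        g = feat["geometry"]
        trees.append(TreeRecord(tree_id=str(p["tree_id"]),
                                row_index=int(p["row_index"]),
                                position_in_row=int(p["position_in_row"]),
                                world_xy=(g.x, g.y)))
    return trees


def cmd_detect(config: RunConfig, manifest: RunManifest | None = None):
    """Crop each tree circle, run the detector, and persist per-tree counts
    plus all detections (scene pixel coordinates)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with _stage(manifest, "detect") as st:
        raster_path = config._default("raster_path", "scene.tif")
        if not raster_path.exists():
            raise FileNotFoundError(f"raster not found: {raster_path}")
        trees = _load_trees(config)
        raster = read_raster(raster_path)
        detector = make_reference_detector(config.detector)
        from .detection import count_per_tree
        counts, detections = count_per_tree(raster, trees, detector,
                                            config.diameter_m,
                                            config.score_floor)
        # detections are tile-local; shift into scene coordinates for persistence
        from .geodata import crop_tree_tile
        det_rows = []
        for tree in trees:
            dets = detections.get(str(tree.tree_id))
            if dets is None:
                continue
            dx, dy = crop_tree_tile(raster, tree, config.diameter_m).window_offset
            for b in dets.boxes:
                det_rows.append({"image_id": str(tree.tree_id),
                                 "xmin": b.xmin + dx, "ymin": b.ymin + dy,
                                 "xmax": b.xmax + dx, "ymax": b.ymax + dy,
                                 "score": b.score})
        count_rows = [{"tree_id": t.tree_id, "row_index": t.row_index,
                       "position_in_row": t.position_in_row,
                       "detected": counts[str(t.tree_id)]}
                      for t in trees]
        pd.DataFrame(count_rows).to_csv(out / "per_tree_counts.csv", index=False)
        pd.DataFrame(det_rows, columns=["image_id", "xmin", "ymin", "xmax",
                                        "ymax", "score"]
                     ).to_csv(out / "detections.csv", index=False)
        st.records = len(count_rows)
    return counts, detections


def cmd_evaluate(config: RunConfig, manifest: RunManifest | None = None):
    """Match persisted detections against truth boxes per tree tile and
    write the per-picture metrics table (TP, FP, FN, P, R, F1, Nfp, A)."""
    out = Path(config.output_dir)
    with _stage(manifest, "evaluate") as st:
        truth_path = config._default("truth_voc_path", "truth_boxes.xml")
        raster_path = config._default("raster_path", "scene.tif")
        for p in (truth_path, raster_path, out / "detections.csv"):
            if not Path(p).exists():
                raise FileNotFoundError(f"evaluate stage input missing: {p}")
        truth = read_voc(truth_path)
        raster = read_raster(raster_path)
        trees = _load_trees(config)
        dets = pd.read_csv(out / "detections.csv")
        radius = config.diameter_m / 2.0
        rows = []
        for tree in trees:
            # truth boxes whose centers fall inside this tree's circle
            tb = []
            for b in truth.boxes:
                col, row = (b.xmin + b.xmax) / 2.0, (b.ymin + b.ymax) / 2.0
                from .geodata import pixel_to_world
                x, y = pixel_to_world(raster.transform, (col, row))
                if (x - tree.world_xy[0]) ** 2 + (y - tree.world_xy[1]) ** 2 <= radius ** 2:
                    tb.append(b)
            sub = dets[dets["image_id"] == str(tree.tree_id)]
            db = [BBox(r.xmin, r.ymin, r.xmax, r.ymax, score=r.score)
                  for r in sub.itertuples()]
            match = match_detections(db, tb, config.iou_min)
            rows.append(detection_metrics(match, nfp=len(tb),
                                          picture_id=str(tree.tree_id)))
        table = metrics_table(rows, presented=True)
        table.to_csv(out / "metrics.csv")
        st.records = len(rows)
    return table


def cmd_calibrate(config: RunConfig, manifest: RunManifest | None = None):
    """Fit the visible-to-total calibration regression.

    Pairs come from ``calibration_csv`` (columns tree_id, detected,
    reference) when given, otherwise from the persisted per-tree detected
    counts joined with the simulated truth totals.
    """
    out = Path(config.output_dir)
    with _stage(manifest, "calibrate") as st:
        if config.calibration_csv:
            pairs_df = pd.read_csv(config.calibration_csv)
        else:
            counts = pd.read_csv(out / "per_tree_counts.csv")
            truth = pd.read_csv(out / "truth_trees.csv")
            pairs_df = counts.merge(truth[["tree_id", "total"]], on="tree_id")
            pairs_df = pairs_df.rename(columns={"total": "reference"})
        pairs = [CalibrationPair(str(r.tree_id), int(r.detected), int(r.reference))
                 for r in pairs_df.itertuples() if not pd.isna(r.detected)]
        fit = fit_calibration(pairs)
        predictions = pd.DataFrame({
            "tree_id": [p.tree_id for p in pairs],
            "detected": [p.detected for p in pairs],
            "reference": [p.reference for p in pairs],
            "predicted_total": [predict_total(fit, p.detected) for p in pairs],
        })
        predictions.to_csv(out / "calibration_predictions.csv", index=False)
        report = {"slope": fit.slope, "intercept": fit.intercept,
                  "r_squared": fit.r_squared, "mae": fit.mae,
                  "rmse": fit.rmse, "n": fit.n}
        (out / "calibration_fit.json").write_text(json.dumps(report, indent=1))
        st.records = len(pairs)
    return fit


def cmd_map(config: RunConfig, manifest: RunManifest | None = None):
    """Build the per-tree and per-row yield layers from the persisted
    per-tree detected counts; written as both GeoJSON and Shapefile."""
    out = Path(config.output_dir)
    with _stage(manifest, "map") as st:
        counts_path = out / "per_tree_counts.csv"
        if not counts_path.exists():
            raise FileNotFoundError(f"map stage input missing: {counts_path}")
        trees = _load_trees(config)
        counts_df = pd.read_csv(counts_path)
        counts = {str(r.tree_id): (None if pd.isna(r.detected) else int(r.detected))
                  for r in counts_df.itertuples()}
        tree_feats = per_tree_layer(trees, counts, config.bin_edges)
        row_feats = per_row_layer(tree_feats)
        crs = config.orchard.crs
        write_vector(tree_feats, out / "yield_per_tree.geojson", crs=crs)
        write_vector(tree_feats, out / "yield_per_tree.shp", crs=crs)
        write_vector(row_feats, out / "yield_per_row.geojson", crs=crs)
        write_vector(row_feats, out / "yield_per_row.shp", crs=crs)
        st.records = len(tree_feats) + len(row_feats)
    return tree_feats, row_feats


def cmd_run_all(config: RunConfig) -> RunManifest:
    """Run every stage in order and write the manifest."""
    manifest = RunManifest(config=config.snapshot(), seed=config.seed)
    cmd_simulate(config, manifest)
    cmd_detect(config, manifest)
    cmd_evaluate(config, manifest)
    cmd_calibrate(config, manifest)
    cmd_map(config, manifest)
    manifest.write(Path(config.output_dir) / "manifest.json")
    return manifest
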