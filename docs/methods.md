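# Methods

This note documents the models, conventions and design choices behind
`orchardyield`, and what the synthetic experiments do and do not show about
real orchard imagery.

## Geospatial conventions

Rasters are north-up with a 6-term affine of which the two shear terms are
fixed at zero: world x = origin_x + col·gsd, world y = origin_y − row·gsd.
Continuous pixel coordinates are 0-based with (0, 0) at the outer corner of
the top-left pixel, so pixel centers sit at half-integers; pixel windows are
half-open. The world→pixel map is the exact algebraic inverse of
pixel→world (round-trip error < 1 nm in tests). Reprojection, rotated
affines and >3-band imagery are out of scope.

A pixel belongs to a circular tree mask iff its *center* lies within the
circle — the common zonal-statistics rule, unambiguous and
oracle-checkable by brute force. Per-tree tiles are the tight window of the
mask intersected with the raster; pixels outside the mask are set to 0 in
all channels (the mask's purpose is to exclude canopy edges and
neighbouring trees, so out-of-circle content must not reach the detector).
Masking is idempotent: cropping a crop with the same circle is the
identity.

GeoTIFF I/O uses `tifffile` with the standard ModelPixelScale and
ModelTiepoint tags; the CRS is carried as an opaque string (stored in the
image description, written to `.prj` for shapefiles) and never
interpreted. Vector I/O supports GeoJSON and ESRI Shapefile; the shapefile
codec is implemented in-package (`esri_shapefile.py`: point, polyline,
polygon + DBF attributes) and its 10-character DBF field-name limit is
handled by a documented renaming map returned from every write.

## Bounding boxes and annotations

Internally all boxes are 0-based half-open `[xmin, xmax) × [ymin, ymax)`.
The PASCAL VOC XML dialect (1-based, inclusive maxima) is converted only at
the I/O boundary: VOC `(1, 1, 10, 10)` ↔ internal `(0, 0, 10, 10)`.

Tiling cuts a regular non-overlapping grid of 416 × 416 tiles (detection
training sets for small objects are built this way to avoid resizing);
right/bottom remainder tiles keep their native size. A box is copied into
every tile it intersects and clipped; clipped copies retaining less than
`min_visibility` (default 0.25) of the original area are dropped — a
standard detection-dataset choice; before the filter, the clipped copies
account for the full original area (tested).

Right-angle rotations are defined **clockwise**: pixel (x, y) of a W×H
image maps to (H−1−y, x); 180° and 270° are compositions. The box remap is
verified against a mask-rotation oracle (rasterize box, `np.rot90`, take
extents), so the convention is self-consistent whichever way a future
detector library defines its rotations. Brightness/contrast augmentation is
`clip(round(α·in + β), 0, 255)` applied uniformly to all channels (a
per-channel variant would be a trivial extension; the uniform map is the
conventional α/β "contrast/brightness" operator). Dataset expansion is
deterministic: originals, then rotated copies, then the intensity variant;
a factor-3 recipe maps 1,000 tiles to exactly 3,000.

## Detection

The detector is a contract: any callable `RGB tile -> DetectionSet`
(deterministic implementations yield deterministic pipelines; boxes are
returned sorted by descending score, ties broken by (ymin, xmin)). The
shipped reference detector is classical: RGB→HSV, threshold on a wrap-around
hue window (default 335°–25°, i.e. red), saturation ≥ 0.35 and value ≥ 0.15;
8-connected components; area and circularity (4πA/P²) filters; per-component
tight bbox scored by circularity capped at 1; greedy NMS at IoU 0.5. The
score is a bounded, monotone proxy for "fruit-likeness" of rendered disks —
explicitly *not* a calibrated probability. The counting threshold
`score_floor` defaults to 0.5; counts are non-increasing in it and in the
mask diameter (both tested).

Per-tree counting crops each tree circle, runs the detector and counts
boxes at or above the score floor. A failed crop (tree outside the raster)
is logged and reported as a missing count rather than aborting the batch.

## Evaluation

Matching is greedy one-to-one: detections in descending score order each
take the unmatched truth box of highest IoU, subject to IoU ≥ `iou_min`
(default 0.5 — the community default for this metric family; the matching
rule is configuration, not dogma). IoU ties are broken by the truth box's
(ymin, xmin). Greedy matching can in principle lose pairs a maximum
assignment would keep; an exhaustive-optimum oracle confirms equality on
hundreds of random ≤6-box instances, and the crossing configurations where
they could differ cost at most one pair.

Per-picture metrics: precision TP/(TP+FP), recall TP/(TP+FN), F1, and
accuracy TP/Nfp with Nfp the manual fruit count of the picture. Undefined
ratios (no detections) are reported as missing, never silently zero; a
positive TP with Nfp = 0 is an inconsistency error. All arithmetic is
unrounded; *presentation* rounding is 2 decimals, half-up, which is what
reproduces every printed cell of the bundled benchmark tables. The `Avg`
row is the arithmetic column mean of unrounded values.

MAE and RMSE follow their standard definitions over paired series; OLS fits
use `scipy.stats.linregress` with R² = 1 − SSres/SStot (for simple OLS with
intercept this equals the squared Pearson correlation, so both common
readings coincide).

## Synthetic orchard generator

The generator emulates the study system the pipeline targets, and its
defaults are the study conditions, chosen once:

| parameter | default | rationale |
|---|---|---|
| layout | 14 rows × 41 trees, 3 m × 1 m | measured orchard geometry |
| `total_count_range` | uniform (202, 308) | only min/max/mean of per-tree totals are reported; uniform on the printed range (175, 308) would give mean 241.5, so the range is recentred to hit the printed mean ≈ 255 while keeping the max — the min is the least-constrained quantity |
| `stratum_mean_fractions` | (0.2731, 0.3763, 0.3506) | published mean top/middle/underside shares |
| `stratum_concentration` | 35 | Dirichlet concentration giving a per-tree top-share s.d. of ≈ 0.07, matching the spread of the published per-tree shares |
| `visibility_probs` | (0.9, 0.3, 0.05) | top fruits nearly always visible from nadir, middle partially, underside almost never; overall expected visible fraction ≈ 0.37, consistent with the field observation that 60–70 % of a tree's crop is visible *from the outside* of which top-view imagery sees a part |
| `gsd_m` | 0.00418 | orthomosaic ground sample distance |
| `canopy_diameter_m` | 1.0 | matches the 1 m masking circle and the 1 m intra-row spacing |
| `fruit_diameter_m` | 0.07 | typical apple |

Per tree, the total is a uniform integer draw; stratum fractions are
Dirichlet with the configured mean and concentration; fraction→integer
conversion uses largest-remainder apportionment (deterministic, sum-exact,
ties to the lower index), so stratum counts always sum to the total. Fruits
are placed uniformly in the canopy disk and may overlap (overlapping fruit
clusters are a real feature of orchard imagery, and the dominant failure
mode of the blob detector). Visibility is independent Bernoulli per fruit
with its stratum's probability. Rendering paints canopy and fruit disks by
the same pixel-center rule as masking, adds optional Gaussian pixel noise,
and records the tight pixel bbox of every visible fruit; a subpixel fruit
is guaranteed at least the pixel containing its center. A configurable
pixel budget (default 64 MP) rejects accidental full-field renders at
4.18 mm/px; tests use small layouts at 5–10 mm/px. Identical
(config, seed) runs are bit-identical.

What the generator does **not** emulate: photorealistic texture, foliage
occlusion geometry, illumination variation, rolling-shutter distortion and
immature (green) fruit. Perfect clean-scene detection scores therefore
validate the *pipeline bookkeeping* (geometry, masking, matching, counting),
not real-world detector performance.

## Calibration and the attenuation caveat

`fit_calibration` regresses reference totals on detected counts — the
direction needed to predict totals from imagery — and `predict_total`
rounds predictions half-up and clamps at zero. On synthetic data the
detected count is a noisy proxy of (visible fraction × total): Bernoulli
visibility and per-tree Dirichlet fraction variation act as
errors-in-variables. With the default conditions the conditional noise
variance of the detected count (≈ 255 at a 255-fruit tree) is comparable to
the signal variance f²·var(total) ≈ 123, so the OLS slope is *attenuated*
far below the naive generative inverse 1/f ≈ 2.79 (measured ≈ 0.8–1.0 at
n = 200). This is a real statistical property of such calibrations, not an
implementation defect: the OLS fit remains the correct *predictor* (its
held-out mean absolute prediction error shrinks as the calibration sample
grows from 20 to 200 trees, verified as averages over replicate calibration
draws because a single 20-tree draw is noise-dominated). A user who wants
the visible fraction itself should regress detected on reference, which
estimates f without attenuation.

## Yield maps

The per-tree layer is a point feature per tree (count, half-open class bin
`[e_k, e_{k+1})`; edges are user configuration, with a default set that
includes the conventional [30, 40) class), ordered by (row, position). The
per-row layer sums counts per row over a thin buffered line from the first
to the last tree (a display choice; block polygons would carry the same
attributes). Row totals conserve tree counts exactly, and binning
partitions the counts. Both layers round-trip through GeoJSON and
Shapefile.

## Problem sizes

Tests and the acceptance script run simulated scenes of 1–15 trees at
5–10 mm/px, calibration experiments of 20–500 trees (count sampling without
rendering is cheap at any size), 500 random matching instances and 200
random NMS sets against exhaustive oracles, and a 1,000-tile augmentation
sweep at 32 × 32 px — sizes at which every oracle is exact and the whole
suite runs in well under a minute.
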