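"""Yield-map layers: a per-tree point layer with count class bins and a
per-row aggregate layer, both writable as Shapefile or GeoJSON through
:func:`orchardyield.geodata.write_vector`.

Features are ``{"geometry": <shapely geometry>, "properties": {...}}``
mappings. Count class bins are half-open intervals ``[e_k, e_{k+1})`` over a
user-supplied edge sequence; a count outside all bins gets the open label
``"<e_0"`` or ``">=e_last"`` so binning always partitions the counts.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from shapely.geometry import LineString, Point

from .evaluation import round_half_up

__all__ = [
    "DEFAULT_BIN_EDGES",
    "bin_label",
    "per_tree_layer",
    "per_row_layer",
    "bin_fraction",
]

# default class bins for per-tree fruit counts; includes the [30, 40) class
DEFAULT_BIN_EDGES = (0, 10, 20, 30, 40, 60, 80, 120, 200, 400)


def bin_label(count: float, bin_edges: Sequence[float]) -> str:
    """Label of the half-open bin ``[e_k, e_{k+1})`` containing ``count``."""
    edges = sorted(bin_edges)
    if len(edges) < 2:
        raise ValueError("need at least two bin edges")
    if count < edges[0]:
        return f"<{edges[0]:g}"
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo <= count < hi:
            return f"[{lo:g},{hi:g})"
    return f">={edges[-1]:g}"


def per_tree_layer(trees: Sequence, counts: Mapping[str, int],
                   bin_edges: Sequence[float] = DEFAULT_BIN_EDGES
                   ) -> list[dict]:
    """One point feature per tree carrying its fruit count and class bin.

    ``trees`` are records with ``tree_id``, ``row_index``,
    ``position_in_row`` and ``world_xy``; ``counts`` maps tree_id to a
    nonnegative count. Features are ordered by (row_index, position_in_row).
    A tree without a count is an error naming it.
    """
    features = []
    for tree in sorted(trees, key=lambda t: (t.row_index, t.position_in_row)):
        tid = str(tree.tree_id)
        if tid not in counts or counts[tid] is None:
            raise ValueError(f"no fruit count for tree {tid!r}")
        count = int(counts[tid])
        if count < 0:
            raise ValueError(f"tree {tid!r}: negative count {count}")
        features.append({
            "geometry": Point(*tree.world_xy),
            "properties": {
                "tree_id": tid,
                "row_index": int(tree.row_index),
                "position_in_row": int(tree.position_in_row),
                "fruit_count": count,
                "class_bin": bin_label(count, bin_edges),
            },
        })
    return features


def per_row_layer(per_tree_features: Sequence[dict],
                  buffer_m: float = 0.5) -> list[dict]:
    """Aggregate the per-tree layer into one feature per row.

    Each row's fruit count is the sum over its trees; its geometry is the
    line from the first to the last tree of the row, buffered to a thin
    polygon for display (a degenerate single-tree row stays a buffered
    point).
    """
    rows: dict[int, list[dict]] = {}
    for feat in per_tree_features:
        rows.setdefault(int(feat["properties"]["row_index"]), []).append(feat)
    features = []
    for row_index in sorted(rows):
        feats = sorted(rows[row_index],
                       key=lambda f: f["properties"]["position_in_row"])
        total = sum(f["properties"]["fruit_count"] for f in feats)
        first, last = feats[0]["geometry"], feats[-1]["geometry"]
        if first.equals(last):
            geometry = first.buffer(buffer_m, quad_segs=8)
        else:
            geometry = LineString([first, last]).buffer(buffer_m, quad_segs=8)
        features.append({
            "geometry": geometry,
            "properties": {"row_index": row_index, "fruit_count": int(total),
                           "n_trees": len(feats)},
        })
    return features


def bin_fraction(counts: Sequence[float], lo: float, hi: float,
                 presented: bool = True) -> float:
    """Percentage of trees whose count lies in the half-open ``[lo, hi)``."""
    counts = list(counts)
    if not counts:
        raise ValueError("bin_fraction needs at least one count")
    frac = 100.0 * sum(1 for c in counts if lo <= c < hi) / len(counts)
    return round_half_up(frac) if presented else frac
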