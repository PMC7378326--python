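"""Minimal ESRI Shapefile I/O for the geometries this package emits.

Supports Point, PolyLine and Polygon records plus a dBASE III (.dbf)
attribute table and the .shx index. This covers the tree-layer and
yield-map deliverables; it is not a general shapefile library (no M/Z
values, no multipatch, no holes in polygons, no codepages beyond ASCII).

DBF field names are limited to 10 bytes by the format; longer attribute
names are truncated and de-duplicated, and the full renaming map
(original name -> written name) is returned by :func:`write`.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Sequence

from shapely.geometry import (
    LineString,
    MultiLineString,
    Point,
    Polygon,
)

SHAPE_NULL = 0
SHAPE_POINT = 1
SHAPE_POLYLINE = 3
SHAPE_POLYGON = 5

_FILE_CODE = 9994
_VERSION = 1000


def truncate_field_names(names: Sequence[str]) -> dict[str, str]:
    """Map attribute names to unique <=10-char DBF field names."""
    mapping: dict[str, str] = {}
    used: set[str] = set()
    for name in names:
        short = str(name)[:10]
        if short.lower() in used:
            stem, k = short[:8], 1
            while f"{stem}_{k}".lower() in used:
                k += 1
                stem = short[: 10 - 1 - len(str(k))]
            short = f"{stem}_{k}"
        used.add(short.lower())
        mapping[str(name)] = short
    return mapping


def _signed_area(coords) -> float:
    s = 0.0
    for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
        s += x0 * y1 - x1 * y0
    return 0.5 * s


def _geometry_record(geom) -> bytes:
    """Serialize one shapely geometry as shapefile record content."""
    if isinstance(geom, Point):
        return struct.pack("<idd", SHAPE_POINT, geom.x, geom.y)
    if isinstance(geom, (LineString, MultiLineString, Polygon)):
        if isinstance(geom, LineString):
            shape_type, parts = SHAPE_POLYLINE, [list(geom.coords)]
        elif isinstance(geom, MultiLineString):
            shape_type, parts = SHAPE_POLYLINE, [list(g.coords) for g in geom.geoms]
        else:
            ring = list(geom.exterior.coords)
            if _signed_area(ring) > 0:     # ESRI outer rings run clockwise
                ring = ring[::-1]
            shape_type, parts = SHAPE_POLYGON, [ring]
        xs = [x for part in parts for x, _ in part]
        ys = [y for part in parts for _, y in part]
        n_points = sum(len(p) for p in parts)
        buf = struct.pack("<i4d", shape_type, min(xs), min(ys), max(xs), max(ys))
        buf += struct.pack("<2i", len(parts), n_points)
        offset = 0
        for part in parts:
            buf += struct.pack("<i", offset)
            offset += len(part)
        for part in parts:
            for x, y in part:
                buf += struct.pack("<2d", x, y)
        return buf
    raise ValueError(f"unsupported geometry type for shapefile: {geom.geom_type}")


def _parse_record(content: bytes):
    (shape_type,) = struct.unpack_from("<i", content, 0)
    if shape_type == SHAPE_NULL:
        return None
    if shape_type == SHAPE_POINT:
        x, y = struct.unpack_from("<2d", content, 4)
        return Point(x, y)
    if shape_type in (SHAPE_POLYLINE, SHAPE_POLYGON):
        n_parts, n_points = struct.unpack_from("<2i", content, 36)
        parts = list(struct.unpack_from(f"<{n_parts}i", content, 44))
        pts_off = 44 + 4 * n_parts
        flat = struct.unpack_from(f"<{2 * n_points}d", content, pts_off)
        pts = [(flat[2 * i], flat[2 * i + 1]) for i in range(n_points)]
        bounds = parts[1:] + [n_points]
        rings = [pts[a:b] for a, b in zip(parts, bounds)]
        if shape_type == SHAPE_POLYGON:
            return Polygon(rings[0])
        if len(rings) == 1:
            return LineString(rings[0])
        return MultiLineString(rings)
    raise ValueError(f"unsupported shapefile shape type {shape_type}")


def _dbf_fields(features, name_map):
    """Infer (short_name, type_char, length, decimals) per attribute."""
    fields = []
    for name, short in name_map.items():
        values = [f["properties"].get(name) for f in features]
        if all(v is None or isinstance(v, bool) or isinstance(v, int) for v in values):
            fields.append((name, short, "N", 18, 0))
        elif all(v is None or isinstance(v, (int, float)) for v in values):
            fields.append((name, short, "N", 24, 8))
        else:
            width = max([len(str(v)) for v in values if v is not None] + [1])
            fields.append((name, short, "C", min(width, 254), 0))
    return fields


def _write_dbf(path: Path, features, fields) -> None:
    record_len = 1 + sum(f[3] for f in fields)
    header_len = 32 + 32 * len(fields) + 1
    with open(path, "wb") as fh:
        fh.write(struct.pack("<4B", 0x03, 95, 7, 26))
        fh.write(struct.pack("<i2h20x", len(features), header_len, record_len))
        for _, short, ftype, length, dec in fields:
            fh.write(struct.pack("<11s", short.encode("ascii")))
            fh.write(ftype.encode("ascii"))
            fh.write(struct.pack("<4xBB14x", length, dec))
        fh.write(b"\x0d")
        for feat in features:
            fh.write(b" ")
            for name, _, ftype, length, dec in fields:
                v = feat["properties"].get(name)
                if v is None:
                    text = ""
                elif ftype == "N" and dec == 0:
                    text = str(int(v))
                elif ftype == "N":
                    text = f"{float(v):.{dec}f}"
                else:
                    text = str(v)[:length]
                raw = text.encode("ascii", "replace")[:length]
                if ftype == "N":
                    fh.write(raw.rjust(length))
                else:
                    fh.write(raw.ljust(length))
        fh.write(b"\x1a")


def _read_dbf(path: Path) -> list[dict]:
    raw = path.read_bytes()
    n_records, header_len, record_len = struct.unpack_from("<i2h", raw, 4)
    n_fields = (header_len - 33) // 32
    fields = []
    for i in range(n_fields):
        off = 32 + 32 * i
        name = raw[off:off + 11].split(b"\x00")[0].decode("ascii")
        ftype = chr(raw[off + 11])
        length = raw[off + 16]
        dec = raw[off + 17]
        fields.append((name, ftype, length, dec))
    records = []
    for i in range(n_records):
        off = header_len + i * record_len
        if raw[off:off + 1] == b"*":     # deleted
            continue
        off += 1
        props = {}
        for name, ftype, length, dec in fields:
            cell = raw[off:off + length].decode("ascii").strip()
            off += length
            if ftype == "N":
                if cell == "":
                    props[name] = None
                elif dec == 0:
                    props[name] = int(cell)
                else:
                    props[name] = float(cell)
            else:
                props[name] = cell
        records.append(props)
    return records


def write(features: Sequence[dict], path, crs: str = "") -> dict[str, str]:
    """Write ``{"geometry", "properties"}`` features to ``path`` (.shp).

    Writes the .shp/.shx/.dbf triple (plus .prj when ``crs`` is given) and
    returns the attribute renaming map imposed by the 10-char DBF limit.
    """
    path = Path(path)
    if not features:
        raise ValueError("cannot write an empty shapefile")
    geoms = [f["geometry"] for f in features]
    records = [_geometry_record(g) for g in geoms]
    shape_types = {struct.unpack_from("<i", r, 0)[0] for r in records}
    if len(shape_types) != 1:
        raise ValueError("shapefile layers must hold a single geometry type")
    shape_type = shape_types.pop()

    minx = min(g.bounds[0] for g in geoms)
    miny = min(g.bounds[1] for g in geoms)
    maxx = max(g.bounds[2] for g in geoms)
    maxy = max(g.bounds[3] for g in geoms)

    total_words = 50 + sum(4 + len(r) // 2 for r in records)
    header = struct.pack(">i5i", _FILE_CODE, 0, 0, 0, 0, 0)
    header += struct.pack(">i", total_words)
    header += struct.pack("<2i", _VERSION, shape_type)
    header += struct.pack("<4d", minx, miny, maxx, maxy)
    header += struct.pack("<4d", 0, 0, 0, 0)

    shx_records = b""
    with open(path, "wb") as fh:
        fh.write(header)
        offset = 50
        for i, rec in enumerate(records, start=1):
            words = len(rec) // 2
            fh.write(struct.pack(">2i", i, words))
            fh.write(rec)
            shx_records += struct.pack(">2i", offset, words)
            offset += 4 + words

    shx_header = bytearray(header)
    shx_header[24:28] = struct.pack(">i", 50 + 4 * len(records))
    path.with_suffix(".shx").write_bytes(bytes(shx_header) + shx_records)

    all_names: list[str] = []
    for f in features:
        for name in f["properties"]:
            if name not in all_names:
                all_names.append(name)
    name_map = truncate_field_names(all_names)
    _write_dbf(path.with_suffix(".dbf"), features, _dbf_fields(features, name_map))
    if crs:
        path.with_suffix(".prj").write_text(crs)
    return name_map


def read(path) -> list[dict]:
    """Read a point/polyline/polygon shapefile back into feature mappings."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 100 or struct.unpack_from(">i", raw, 0)[0] != _FILE_CODE:
        raise ValueError(f"{path}: not a shapefile")
    geoms = []
    off = 100
    while off < len(raw):
        _, words = struct.unpack_from(">2i", raw, off)
        content = raw[off + 8:off + 8 + 2 * words]
        geoms.append(_parse_record(content))
        off += 8 + 2 * words
    dbf = path.with_suffix(".dbf")
    props = _read_dbf(dbf) if dbf.exists() else [{} for _ in geoms]
    if len(props) != len(geoms):
        raise ValueError(f"{path}: .shp/.dbf record count mismatch")
    return [{"geometry": g, "properties": p} for g, p in zip(geoms, props)]
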