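"""Class scheme and polygon-label rasterization.

The five-class mapping scheme assigns Healthy Moss=1, Stressed Moss=2,
Moribund Moss=3, Lichen=4, Non-Vegetation=5; 0 marks unlabeled/nodata
pixels.  Vector labels (GeoJSON polygons carrying a ``class`` property) are
burned into masks by the pixel-center rule: a pixel takes a polygon's class
iff its center lies inside the polygon, with later polygons overwriting
earlier ones where they overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import shape as shapely_shape, mapping as shapely_mapping

from .bands import IDENTITY_TRANSFORM

__all__ = ["ClassScheme", "DEFAULT_SCHEME", "rasterize_labels", "read_geojson", "write_geojson"]


@dataclass(frozen=True)
class ClassScheme:
    """Bijective name <-> integer-ID class mapping with display colors."""

    names: tuple[str, ...] = (
        "healthy_moss",
        "stressed_moss",
        "moribund_moss",
        "lichen",
        "non_vegetation",
    )
    colors: tuple[str, ...] = ("#1a9641", "#fdae61", "#9e9e9e", "#d7191c", "#bdb76b")

    def __post_init__(self):
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate class names")

    @property
    def ids(self) -> dict[str, int]:
        return {n: i + 1 for i, n in enumerate(self.names)}

    @property
    def n_classes(self) -> int:
        return len(self.names)

    def id_of(self, name: str) -> int:
        try:
            return self.ids[name]
        except KeyError:
            raise KeyError(f"unknown class {name!r}; scheme classes: {list(self.names)}")

    def name_of(self, cid: int) -> str:
        if not 1 <= cid <= len(self.names):
            raise KeyError(f"class ID {cid} outside 1..{len(self.names)}")
        return self.names[cid - 1]


DEFAULT_SCHEME = ClassScheme()


def rasterize_labels(
    polygons: list[tuple[object, str]],
    shape: tuple[int, int],
    scheme: ClassScheme = DEFAULT_SCHEME,
    transform: tuple[float, ...] = IDENTITY_TRANSFORM,
) -> np.ndarray:
    """Burn (geometry, class-name) pairs into an integer label mask.

    Geometries are shapely objects in the raster's world coordinates;
    ``transform`` maps (col, row) pixel indices to world coordinates.
    Untouched pixels stay 0.
    """
    h, w = shape
    out = np.zeros((h, w), dtype=np.int64)
    a, b, c0, d, e, f = transform
    cols, rows = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    xs = a * cols + b * rows + c0
    ys = d * cols + e * rows + f
    for geom, cls_name in polygons:
        cid = scheme.id_of(cls_name)
        if not isinstance(geom, shapely.Geometry):
            geom = shapely_shape(geom)
        if geom.is_empty:
            continue
        minx, miny, maxx, maxy = geom.bounds
        # cheap bbox pre-filter keeps contains_xy calls local
        box = (xs >= minx) & (xs <= maxx) & (ys >= miny) & (ys <= maxy)
        if not box.any():
            continue
        inside = shapely.contains_xy(geom, xs[box], ys[box])
        sel = np.zeros((h, w), dtype=bool)
        sel[box] = inside
        out[sel] = cid
    return out


def read_geojson(path) -> list[tuple[object, str]]:
    """Load (geometry, class-name) pairs from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        data = json.load(fh)
    out = []
    for feat in data.get("features", []):
        out.append((shapely_shape(feat["geometry"]), feat["properties"]["class"]))
    return out


def write_geojson(path, polygons: list[tuple[object, str]]) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": shapely_mapping(geom),
            "properties": {"class": cls},
        }
        for geom, cls in polygons
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
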