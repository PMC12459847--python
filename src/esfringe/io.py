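"""File I/O for the formats the pipeline touches.

Rasters are stored as ESRI ASCII grids (plain text, one file per layer),
villages and POIs as GeoJSON, tables as UTF-8 comma-separated CSV with '.'
decimals and mandatory headers, configuration as YAML.  Coordinates are
planar metres; the grid origin is the top-left cell corner and the header's
``yllcorner`` records the origin's y (rows grow downward from it).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point, box, mapping, shape
from shapely.ops import unary_union

from .grids import NODATA, AlignmentError, RasterLayer, VillageTessellation


# ---------------------------------------------------------------------------
# rasters (ESRI ASCII grid)


def write_raster(layer: RasterLayer, path: str | Path) -> Path:
    """Write one layer as an ESRI ASCII grid; NaN becomes the nodata sentinel."""
    path = Path(path)
    rows, cols = layer.shape
    vals = np.where(np.isfinite(layer.values), layer.values, layer.nodata)
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {layer.origin[0]!r}\n"
        f"yllcorner {layer.origin[1]!r}\n"
        f"cellsize {layer.cell_size_m!r}\n"
        f"NODATA_value {layer.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.17g")
    return path


def read_raster(path: str | Path, name: str | None = None,
                units: str = "") -> RasterLayer:
    """Read an ESRI ASCII grid written by :func:`write_raster`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"malformed raster {path}: shape/header mismatch")
    nodata = header.get("nodata_value", NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    return RasterLayer(
        values=vals,
        name=name or path.stem,
        units=units,
        nodata=nodata,
        cell_size_m=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )


def check_companions(layers: list[RasterLayer]) -> None:
    """Raise AlignmentError unless all layers share grid, cell size, origin."""
    ref = layers[0]
    for layer in layers[1:]:
        ref.check_aligned(layer)


# ---------------------------------------------------------------------------
# vectors (GeoJSON)


def village_polygons(villages: VillageTessellation) -> dict[int, object]:
    """Shapely polygon per village: the union of its coarse cell boxes."""
    out: dict[int, object] = {}
    cs = villages.cell_size_m
    ox, oy = villages.origin
    for vid in villages.ids:
        cells = np.argwhere(villages.labels == vid)
        boxes = [
            box(ox + j * cs, oy + i * cs, ox + (j + 1) * cs, oy + (i + 1) * cs)
            for i, j in cells
        ]
        out[int(vid)] = unary_union(boxes)
    return out


def write_villages(villages: VillageTessellation, path: str | Path) -> Path:
    path = Path(path)
    polys = village_polygons(villages)
    features = [
        {
            "type": "Feature",
            "properties": {"id": vid},
            "geometry": mapping(geom),
        }
        for vid, geom in polys.items()
    ]
    gj = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {
            "cell_size_m": villages.cell_size_m,
            "origin": list(villages.origin),
            "grid_shape": list(villages.labels.shape),
        },
    }
    path.write_text(json.dumps(gj))
    return path


def read_villages(path: str | Path) -> VillageTessellation:
    """Read villages written by :func:`write_villages`, rasterising by cell centre."""
    gj = json.loads(Path(path).read_text())
    props = gj.get("properties", {})
    cs = float(props["cell_size_m"])
    ox, oy = props["origin"]
    rows, cols = props["grid_shape"]
    geoms = []
    for feat in gj["features"]:
        geom = shape(feat["geometry"])
        if geom.is_empty:
            raise ValueError("empty village geometry")
        geoms.append((int(feat["properties"]["id"]), geom))
    for i in range(len(geoms)):
        for j in range(i + 1, len(geoms)):
            inter = geoms[i][1].intersection(geoms[j][1])
            if inter.area > 1e-9 * cs * cs:
                raise ValueError(
                    f"villages {geoms[i][0]} and {geoms[j][0]} overlap"
                )
    labels = np.zeros((rows, cols), dtype=int)
    for i in range(rows):
        for j in range(cols):
            p = Point(ox + (j + 0.5) * cs, oy + (i + 0.5) * cs)
            for vid, geom in geoms:
                if geom.contains(p):
                    labels[i, j] = vid
                    break
            else:
                raise ValueError(f"cell ({i},{j}) not covered by any village")
    ids = np.array(sorted(v for v, _ in geoms))
    return VillageTessellation(labels=labels, ids=ids, cell_size_m=cs,
                               origin=(ox, oy))


def write_poi(poi: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    features = [
        {
            "type": "Feature",
            "properties": {"category": str(rec.category)},
            "geometry": {"type": "Point", "coordinates": [rec.x, rec.y]},
        }
        for rec in poi.itertuples()
    ]
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def read_poi(path: str | Path) -> pd.DataFrame:
    gj = json.loads(Path(path).read_text())
    rows = []
    for feat in gj["features"]:
        x, y = feat["geometry"]["coordinates"]
        rows.append({"x": x, "y": y, "category": feat["properties"]["category"]})
    return pd.DataFrame(rows, columns=["x", "y", "category"])


# ---------------------------------------------------------------------------
# tables and config


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    df.to_csv(path, index=index)
    return path


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, **kwargs)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(data: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path
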