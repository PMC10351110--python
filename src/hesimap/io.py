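"""Readers and writers for the pipeline's on-disk formats.

GeoTIFF (single band, float32 or int32, explicit nodata) for rasters,
CSV for tabular data, GeoJSON for zone polygons, YAML for configs.
GeoTIFFs are written with the standard ModelPixelScale / ModelTiepoint /
GDAL_NODATA tags so they round-trip through GDAL-based tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import box, shape, mapping
from shapely.ops import unary_union

from .grids import GridTransform, RasterGrid

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

FLOAT_NODATA = -9999.0


def write_raster(path: str | Path, grid: RasterGrid) -> None:
    """Write a single-band GeoTIFF with geotransform and nodata tags."""
    t = grid.transform
    data = grid.data
    if np.issubdtype(data.dtype, np.floating):
        out = np.where(np.isnan(data), FLOAT_NODATA, data).astype(np.float32)
        nodata = FLOAT_NODATA
    else:
        out = data.astype(np.int32)
        nodata = grid.nodata_int
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (t.cell_size, t.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.origin_x, t.origin_y, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(str(path), out, extratags=extratags)


def read_raster(path: str | Path, name: str | None = None) -> RasterGrid:
    """Read a GeoTIFF written by :func:`write_raster` (or GDAL-compatible)."""
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        try:
            sx, sy, _ = tags[_TAG_PIXEL_SCALE].value[:3]
            tie = tags[_TAG_TIEPOINT].value
        except KeyError as exc:
            raise ValueError(f"{path}: missing geotransform tags") from exc
        origin_x, origin_y = float(tie[3]), float(tie[4])
        nodata_tag = tags.get(_TAG_GDAL_NODATA)
        nodata = float(nodata_tag.value) if nodata_tag is not None else None
    transform = GridTransform(origin_x, origin_y, float(sx))
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float64)
        if nodata is not None:
            data[data == nodata] = np.nan
        return RasterGrid(data, transform, name=name or path.stem)
    grid = RasterGrid(data.astype(np.int64), transform, name=name or path.stem)
    if nodata is not None:
        grid.nodata_int = int(nodata)
    return grid


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path)
    if required:
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    return table


# ---------------------------------------------------------------------------
# Zone polygons


def zones_to_geojson(zones: RasterGrid, id_property: str = "zone_id") -> dict:
    """Polygonize a zone-label raster into a GeoJSON FeatureCollection.

    Each zone becomes the union of its member cell rectangles.
    """
    t = zones.transform
    features = []
    labels = np.unique(zones.data[~zones.mask])
    for label in labels:
        rows, cols = np.nonzero(zones.data == label)
        cells = [
            box(
                t.origin_x + c * t.cell_size,
                t.origin_y - (r + 1) * t.cell_size,
                t.origin_x + (c + 1) * t.cell_size,
                t.origin_y - r * t.cell_size,
            )
            for r, c in zip(rows, cols)
        ]
        geom = unary_union(cells)
        features.append(
            {
                "type": "Feature",
                "properties": {id_property: int(label)},
                "geometry": mapping(geom),
            }
        )
    return {"type": "FeatureCollection", "features": features}


def rasterize_zones(
    geojson: dict,
    transform: GridTransform,
    shape_: tuple[int, int],
    id_property: str = "zone_id",
) -> RasterGrid:
    """Burn zone polygons onto the grid; boundary cells go to the polygon
    with the largest overlap area (majority-cell rule)."""
    nrow, ncol = shape_
    labels = np.full(shape_, -1, dtype=np.int64)
    best_area = np.zeros(shape_)
    cs = transform.cell_size
    for feat in geojson["features"]:
        geom = shape(feat["geometry"])
        label = int(feat["properties"][id_property])
        minx, miny, maxx, maxy = geom.bounds
        c0 = max(0, int(np.floor((minx - transform.origin_x) / cs)))
        c1 = min(ncol - 1, int(np.ceil((maxx - transform.origin_x) / cs)))
        r0 = max(0, int(np.floor((transform.origin_y - maxy) / cs)))
        r1 = min(nrow - 1, int(np.ceil((transform.origin_y - miny) / cs)))
        for r in range(r0, r1 + 1):
            for c in range(c0, c1 + 1):
                cell = box(
                    transform.origin_x + c * cs,
                    transform.origin_y - (r + 1) * cs,
                    transform.origin_x + (c + 1) * cs,
                    transform.origin_y - r * cs,
                )
                area = geom.intersection(cell).area
                if area > best_area[r, c]:
                    best_area[r, c] = area
                    labels[r, c] = label
    return RasterGrid(labels, transform, name="zones")


def write_geojson(path: str | Path, collection: dict) -> None:
    Path(path).write_text(json.dumps(collection))


def read_geojson(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_yaml(path: str | Path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path: str | Path):
    return yaml.safe_load(Path(path).read_text())


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, np.bool_):
        return bool(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
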