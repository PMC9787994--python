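"""Reading and writing the pipeline's exchange formats.

All tabular exchange is CSV (UTF-8, '.' decimal, header row); rasters
are ESRI ASCII grids; polygons GeoJSON; point clouds XYZ CSV with
columns x, y, height.  Readers validate schemas and report the
offending column or row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .structure import CanopyGrid

__all__ = [
    "write_esri_ascii",
    "read_esri_ascii",
    "write_points_xyz",
    "read_points_xyz",
    "read_polygon_geojson",
    "write_polygon_geojson",
    "read_survey",
    "read_compartments",
    "read_detectability",
    "read_traits",
]

_NODATA = -9999.0


def write_esri_ascii(grid: CanopyGrid, path) -> None:
    """Write a canopy grid as an ESRI ASCII raster."""
    ny, nx = grid.cells.shape
    x0, y0 = grid.origin
    cells = np.where(np.isnan(grid.cells), _NODATA, grid.cells)
    header = (
        f"ncols {nx}\n"
        f"nrows {ny}\n"
        f"xllcorner {x0}\n"
        f"yllcorner {y0 - ny * grid.resolution}\n"
        f"cellsize {grid.resolution}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        np.savetxt(fh, cells, fmt="%.4f")


def read_esri_ascii(path, expected_resolution: float | None = None) -> CanopyGrid:
    """Read an ESRI ASCII raster into a canopy grid."""
    meta = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                fh.seek(pos)
                break
            meta[parts[0].lower()] = float(parts[1])
        cells = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in meta:
            raise ValueError(f"{path}: missing header field {key!r}")
    res = meta["cellsize"]
    if expected_resolution is not None and abs(res - expected_resolution) > 1e-9:
        raise ValueError(
            f"{path}: cell size {res} does not match expected "
            f"{expected_resolution}"
        )
    nodata = meta.get("nodata_value", _NODATA)
    cells = np.where(cells == nodata, np.nan, cells)
    origin = (meta["xllcorner"], meta["yllcorner"] + meta["nrows"] * res)
    return CanopyGrid(resolution=res, origin=origin, cells=cells)


def write_points_xyz(points: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(points).reshape(-1, 3), columns=["x", "y", "height"]).to_csv(
        path, index=False
    )


def read_points_xyz(path) -> np.ndarray:
    df = pd.read_csv(path)
    missing = {"x", "y", "height"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df[["x", "y", "height"]].to_numpy(dtype=float)


def read_polygon_geojson(path):
    import shapely.geometry

    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        return [
            (f.get("properties", {}), shapely.geometry.shape(f["geometry"]))
            for f in gj["features"]
        ]
    if gj.get("type") == "Feature":
        return [(gj.get("properties", {}), shapely.geometry.shape(gj["geometry"]))]
    return [({}, shapely.geometry.shape(gj))]


def write_polygon_geojson(geometries, path) -> None:
    import shapely.geometry

    features = [
        {
            "type": "Feature",
            "properties": props,
            "geometry": shapely.geometry.mapping(geom),
        }
        for props, geom in geometries
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def _read_csv(path, required: set[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{name} table {path}: missing columns {sorted(missing)}")
    return df


def read_survey(path) -> pd.DataFrame:
    df = _read_csv(
        path, {"compartment_id", "species_id", "visit", "count"}, "survey"
    )
    dup = df.duplicated(["compartment_id", "species_id", "visit"])
    if dup.any():
        raise ValueError(
            f"survey table {path}: duplicate (compartment, species, visit) "
            f"rows at index {list(df.index[dup][:5])}"
        )
    return df


def read_compartments(path) -> pd.DataFrame:
    return _read_csv(
        path, {"compartment_id", "management", "age_class", "area_ha"},
        "compartments",
    )


def read_detectability(path) -> pd.Series:
    df = _read_csv(path, {"species_id", "detectability"}, "detectability")
    return df.set_index("species_id")["detectability"]


def read_traits(path) -> pd.DataFrame:
    df = _read_csv(path, {"species_id"}, "traits")
    return df.set_index("species_id")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
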