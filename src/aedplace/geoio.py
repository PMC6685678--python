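"""Plain-text geospatial IO: GeoJSON feature collections and point CSVs.

GeoJSON is ordinary JSON; geometries are converted to and from shapely via
``shapely.geometry.mapping`` / ``shape``.  Coordinates are WGS84 lon/lat in
degrees throughout (GeoJSON axis order: ``[lon, lat]``).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry


def write_geojson(path: str | Path, geometries: list[BaseGeometry], properties: list[dict]) -> None:
    """Write a GeoJSON FeatureCollection (one feature per geometry)."""
    if len(geometries) != len(properties):
        raise ValueError("geometries and properties must have equal length")
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": props}
        for geom, props in zip(geometries, properties)
    ]
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload))


def read_geojson(path: str | Path) -> tuple[list[BaseGeometry], pd.DataFrame]:
    """Read a FeatureCollection into (geometries, properties DataFrame)."""
    payload = json.loads(Path(path).read_text())
    if payload.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    geoms = [shape(f["geometry"]) for f in payload["features"]]
    props = pd.DataFrame([f.get("properties") or {} for f in payload["features"]])
    return geoms, props


def write_points_csv(path: str | Path, df: pd.DataFrame) -> None:
    """Write a point table with a stable float format (reproducible bytes)."""
    df.to_csv(path, index=False, float_format="%.10g")


def read_points_csv(path: str | Path, id_col: str = "id") -> pd.DataFrame:
    """Read a point CSV requiring ``lat`` and ``lon`` columns."""
    df = pd.read_csv(path)
    missing = {"lat", "lon"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df
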