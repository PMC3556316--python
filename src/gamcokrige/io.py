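"""Readers and writers for the pipeline's plain-text formats.

Sites travel as CSV (id, x, y, count, covariate columns), layers as GeoJSON
(Polygon/MultiPolygon features carrying a ``category`` property, LineString
features carrying a ``kind`` property), variogram and coregionalization
models as JSON, configuration as YAML.  Every writer drops a ``.meta.json``
provenance sidecar next to the output (package version, seed, config hash).
Coordinates are projected planar metres throughout; no CRS transforms are
performed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import LineString, mapping, shape

from . import __version__
from .geo import GeoLayer
from .variograms import VariogramModel

__all__ = [
    "read_sites",
    "write_sites",
    "read_layer_geojson",
    "write_layer_geojson",
    "read_variogram_json",
    "write_variogram_json",
    "read_config_yaml",
    "write_config_yaml",
    "write_provenance",
]

REQUIRED_SITE_COLUMNS = ("id", "x", "y")


def read_sites(path, require_count: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = list(REQUIRED_SITE_COLUMNS) + (["count"] if require_count else [])
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"site table {path} is missing required columns: {missing}")
    return df


def write_sites(df: pd.DataFrame, path, seed=None, config=None) -> None:
    path = Path(path)
    df.to_csv(path, index=False)
    write_provenance(path, seed=seed, config=config)


def write_layer_geojson(layer: GeoLayer, path, seed=None, config=None) -> None:
    features = []
    if layer.kind == "polygon-categorical":
        for geom, cat in layer.polygons:
            features.append(
                {"type": "Feature", "geometry": mapping(geom), "properties": {"category": cat}}
            )
    else:
        for line in layer.lines:
            features.append(
                {"type": "Feature", "geometry": mapping(line), "properties": {"kind": layer.name}}
            )
    doc = {
        "type": "FeatureCollection",
        "name": layer.name,
        "layer_kind": layer.kind,
        "features": features,
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    write_provenance(path, seed=seed, config=config)


def read_layer_geojson(path) -> GeoLayer:
    doc = json.loads(Path(path).read_text())
    kind = doc.get("layer_kind")
    name = doc.get("name", Path(path).stem)
    feats = doc["features"]
    if kind is None:  # infer from the first geometry
        gtype = feats[0]["geometry"]["type"] if feats else "Polygon"
        kind = "polyline" if gtype == "LineString" else "polygon-categorical"
    if kind == "polyline":
        lines = [LineString(shape(f["geometry"])) for f in feats]
        return GeoLayer(kind="polyline", name=name, lines=lines)
    polys = [(shape(f["geometry"]), f["properties"].get("category")) for f in feats]
    return GeoLayer(kind="polygon-categorical", name=name, polygons=polys)


def write_variogram_json(model, path, seed=None, config=None) -> None:
    path = Path(path)
    path.write_text(json.dumps(model.to_dict(), indent=2))
    write_provenance(path, seed=seed, config=config)


def read_variogram_json(path) -> VariogramModel:
    return VariogramModel.from_dict(json.loads(Path(path).read_text()))


def read_config_yaml(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def write_config_yaml(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _config_hash(config) -> str | None:
    if config is None:
        return None
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(artifact_path, seed=None, config=None) -> Path:
    """Sidecar ``<artifact>.meta.json`` recording version, seed and config hash."""
    artifact_path = Path(artifact_path)
    meta = {
        "artifact": artifact_path.name,
        "package": "gamcokrige",
        "version": __version__,
        "seed": None if seed is None else int(seed),
        "config_hash": _config_hash(config),
    }
    side = artifact_path.with_suffix(artifact_path.suffix + ".meta.json")
    side.write_text(json.dumps(meta, indent=2))
    return side
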