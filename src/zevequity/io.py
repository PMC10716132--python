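"""Serialization of region artifacts and results.

All outputs are plain text: GeoJSON for geometries (planar meter
coordinates), headered UTF-8 CSV for tables, JSON for nested reports and
the run manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from zevequity.region import SyntheticRegion


def _feature(geometry: dict, properties: dict) -> dict:
    return {"type": "Feature", "geometry": geometry, "properties": properties}


def write_tracts_geojson(tracts: pd.DataFrame, path: Path) -> None:
    feats = []
    skip = {"x0", "y0", "x1", "y1", "cx", "cy"}
    for row in tracts.to_dict("records"):
        poly = [[[row["x0"], row["y0"]], [row["x1"], row["y0"]],
                 [row["x1"], row["y1"]], [row["x0"], row["y1"]],
                 [row["x0"], row["y0"]]]]
        props = {k: _jsonable(v) for k, v in row.items() if k not in skip}
        feats.append(_feature({"type": "Polygon", "coordinates": poly}, props))
    _write_geojson(feats, path)


def write_links_geojson(links: pd.DataFrame, path: Path) -> None:
    feats = []
    skip = {"x1", "y1", "x2", "y2", "mx", "my"}
    for row in links.to_dict("records"):
        line = [[row["x1"], row["y1"]], [row["x2"], row["y2"]]]
        props = {k: _jsonable(v) for k, v in row.items() if k not in skip}
        feats.append(_feature({"type": "LineString", "coordinates": line},
                              props))
    _write_geojson(feats, path)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    return v


def _write_geojson(features: list, path: Path) -> None:
    path.write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}), encoding="utf-8")


def write_region(region: SyntheticRegion, outdir: Path) -> Dict[str, Path]:
    """Write every region artifact; returns name → path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    paths["tracts"] = outdir / "tracts.geojson"
    write_tracts_geojson(region.tracts, paths["tracts"])
    paths["links"] = outdir / "links.geojson"
    write_links_geojson(region.links, paths["links"])

    trips = region.trips.copy()
    trips["route"] = ["|".join(r) for r in trips["route"]]
    paths["trips"] = outdir / "trips.csv"
    trips.to_csv(paths["trips"], index=False)

    paths["fleet_history"] = outdir / "fleet_history.csv"
    region.fleet_history.to_csv(paths["fleet_history"], index=False)
    paths["met"] = outdir / "met.csv"
    region.met.to_csv(paths["met"], index=False)
    paths["rates"] = outdir / "rates.csv"
    region.rates.to_csv(paths["rates"], index=False)
    paths["weight_map"] = outdir / "weight_map.csv"
    region.weight_map.to_csv(paths["weight_map"], index=False)
    return paths


def read_trips_csv(path: Path) -> pd.DataFrame:
    trips = pd.read_csv(path)
    trips["route"] = [tuple(r.split("|")) for r in trips["route"]]
    return trips


def file_checksum(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_json(obj: dict, path: Path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, default=_jsonable, allow_nan=True),
        encoding="utf-8")
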