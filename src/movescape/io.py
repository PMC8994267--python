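"""File formats, seasons, seed streams and run manifests.

Track CSVs carry ``animal_id, timestamp (ISO 8601), x, y`` in projected
metres.  Rasters are exchanged as ESRI ASCII grids (plain text, nodata
-9999); vector scenes as GeoJSON.  All randomness in a pipeline run flows
from one master seed through named substreams.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from movescape.hmm import Track
from movescape.landscape import GridGeometry, VectorScene

__all__ = [
    "read_tracks",
    "assign_season",
    "season_of_month",
    "write_ascii_grid",
    "read_ascii_grid",
    "write_scene_geojson",
    "read_scene_geojson",
    "seed_stream",
    "SeedRegistry",
    "write_manifest",
]

NODATA = -9999.0

SEASON_MONTHS = {
    5: "spring", 6: "spring",
    7: "summer", 8: "summer",
    9: "fall", 10: "fall",
    1: "winter", 2: "winter",
}


def season_of_month(month: int) -> str | None:
    return SEASON_MONTHS.get(int(month))


def assign_season(timestamp) -> str | None:
    """Biological season of a timestamp: May-Jun spring, Jul-Aug summer,
    Sep-Oct fall, Jan-Feb winter (wolves); other months excluded (None)."""
    ts = pd.Timestamp(timestamp)
    return season_of_month(ts.month)


def read_tracks(csv_path, min_fixes: int = 3) -> list[Track]:
    """Parse a track CSV into per-animal :class:`Track` objects.

    Rows are sorted by animal and time; duplicate timestamps within an
    animal keep the first occurrence; malformed rows are counted and
    skipped.  Animals with fewer than ``min_fixes`` usable fixes are
    dropped with a warning.
    """
    df = pd.read_csv(csv_path)
    required = ["animal_id", "timestamp", "x", "y"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"track CSV missing required column {col!r}")
    if df.empty:
        warnings.warn("empty track file")
        return []
    n_raw = len(df)
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce")
    df["x"] = pd.to_numeric(df["x"], errors="coerce")
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    df = df.dropna(subset=["animal_id", "timestamp", "x", "y"])
    n_malformed = n_raw - len(df)
    if n_malformed:
        warnings.warn(f"skipped {n_malformed} malformed rows")
    df = df.sort_values(["animal_id", "timestamp"], kind="stable")
    before = len(df)
    df = df.drop_duplicates(subset=["animal_id", "timestamp"], keep="first")
    if len(df) < before:
        warnings.warn(f"dropped {before - len(df)} duplicate timestamps")

    tracks = []
    for aid, g in df.groupby("animal_id", sort=True):
        if len(g) < min_fixes:
            warnings.warn(f"animal {aid!r} has fewer than {min_fixes} fixes")
            continue
        season = assign_season(g["timestamp"].iloc[0])
        tracks.append(
            Track(
                animal_id=str(aid),
                timestamps=g["timestamp"].to_numpy().astype("datetime64[s]"),
                x=g["x"].to_numpy(),
                y=g["y"].to_numpy(),
                season=season,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# rasters: ESRI ASCII grid (text)
# ---------------------------------------------------------------------------


def write_ascii_grid(path, values: np.ndarray, geometry: GridGeometry) -> None:
    """Write one raster layer as an ESRI ASCII grid (north row first)."""
    values = np.where(np.isfinite(values), values, NODATA)
    header = (
        f"ncols {geometry.n_cols}\n"
        f"nrows {geometry.n_rows}\n"
        f"xllcorner {geometry.origin_x}\n"
        f"yllcorner {geometry.origin_y}\n"
        f"cellsize {geometry.cell_size}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values[::-1], fmt="%.10g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridGeometry]:
    with open(path) as fh:
        head = {}
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        values = np.loadtxt(fh)
    geom = GridGeometry(
        n_rows=int(head["nrows"]),
        n_cols=int(head["ncols"]),
        cell_size=head["cellsize"],
        origin_x=head["xllcorner"],
        origin_y=head["yllcorner"],
    )
    values = values.reshape(geom.shape)[::-1]
    values = np.where(values == head["nodata_value"], np.nan, values)
    return values, geom


# ---------------------------------------------------------------------------
# vectors: GeoJSON
# ---------------------------------------------------------------------------


def write_scene_geojson(path, scene: VectorScene) -> None:
    feats = []

    def add(geom, kind, **props):
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {"kind": kind, **props},
            }
        )

    for g in scene.towns:
        add(g, "town")
    for cls, g in scene.linear_features:
        add(g, "linear_feature", feature_class=cls)
    for g in scene.patches:
        add(g, "patch")
    for g in scene.transects:
        add(g, "transect")
    if scene.focal_area is not None:
        add(scene.focal_area, "focal_area")
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_scene_geojson(path) -> VectorScene:
    with open(path) as fh:
        fc = json.load(fh)
    towns, feats, patches, transects = [], [], [], []
    focal = None
    for f in fc["features"]:
        geom = shape(f["geometry"])
        kind = f["properties"]["kind"]
        if kind == "town":
            towns.append(geom)
        elif kind == "linear_feature":
            feats.append((f["properties"]["feature_class"], geom))
        elif kind == "patch":
            patches.append(geom)
        elif kind == "transect":
            transects.append(geom)
        elif kind == "focal_area":
            focal = geom
    return VectorScene(
        towns=towns, linear_features=feats, patches=patches,
        transects=transects, focal_area=focal,
    )


# ---------------------------------------------------------------------------
# seeds and manifests
# ---------------------------------------------------------------------------


def seed_stream(master_seed: int, name: str) -> int:
    """Deterministic named substream seed (< 2**31) from a master seed."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


class SeedRegistry:
    """Audit trail of every named seed handed out during a run."""

    def __init__(self, master_seed: int):
        self.master_seed = int(master_seed)
        self.issued: dict[str, int] = {}

    def get(self, name: str) -> int:
        if name not in self.issued:
            self.issued[name] = seed_stream(self.master_seed, name)
        return self.issued[name]


def write_manifest(path, stage: str, seed: int, inputs: dict) -> None:
    """Record a stage's inputs hash and seed for reproducibility auditing."""
    payload = json.dumps(inputs, sort_keys=True, default=str)
    manifest = {
        "stage": stage,
        "seed": seed,
        "inputs_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "inputs": inputs,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
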