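"""Ingest of collar fixes, terrain grids, weather tables and landscape features.

Collar fixes live in a pandas DataFrame with one row per transmission and the
columns of :data:`FIX_COLUMNS`; timestamps are UTC ``datetime64[ns, UTC]``.
Terrain is a lat/lon-aligned elevation grid (ESRI ASCII input); landscape
features (water points, buildings, roads) are GeoJSON parsed into shapely
geometries in WGS84 degrees.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import shape

logger = logging.getLogger(__name__)

#: Canonical fix-table columns, in order.
FIX_COLUMNS = ["collar_id", "herd_id", "species", "timestamp", "lat", "lon",
               "altitude_m", "quality"]

#: The three livestock species handled by the pipeline.
SPECIES = ("bovine", "equine", "ovine")

# Common vernacular names are normalized to the species enums at ingest.
_SPECIES_ALIASES = {
    "bovine": "bovine", "cow": "bovine", "cattle": "bovine",
    "equine": "equine", "horse": "equine",
    "ovine": "ovine", "sheep": "ovine",
}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowError(ValueError):
    """A row failed validation; the message carries the 1-based line number."""


@dataclass
class TerrainGrid:
    """Rectangular elevation grid aligned to geographic (lat/lon) axes.

    ``elevation[i, j]`` is the elevation in meters at
    ``lat = origin_lat + i * cell_size`` and ``lon = origin_lon + j * cell_size``
    (row 0 is the southern edge). ``cell_size`` is in decimal degrees.
    """

    origin_lat: float
    origin_lon: float
    cell_size: float
    elevation: np.ndarray
    crs_tag: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.ndim != 2:
            raise ValueError("elevation must be a 2-D array")
        if not np.all(np.isfinite(self.elevation)):
            raise ValueError("elevation must be finite")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    def bounds(self) -> tuple[float, float, float, float]:
        """(lat_min, lat_max, lon_min, lon_max) covered by grid nodes."""
        nrow, ncol = self.elevation.shape
        return (self.origin_lat, self.origin_lat + (nrow - 1) * self.cell_size,
                self.origin_lon, self.origin_lon + (ncol - 1) * self.cell_size)


def normalize_species(name: str) -> str:
    """Map a species name (case-insensitive, common aliases) to the enum."""
    key = str(name).strip().lower()
    if key not in _SPECIES_ALIASES:
        raise ValueError(f"unknown species {name!r}; expected one of {SPECIES}")
    return _SPECIES_ALIASES[key]


def read_fixes(path, tz_policy: str = "utc") -> pd.DataFrame:
    """Read collar fixes from CSV into the canonical fix table.

    Parameters
    ----------
    path
        CSV with header columns ``collar_id, herd_id, species, timestamp,
        lat, lon`` (ISO-8601 timestamps, WGS84 decimal degrees); optional
        ``altitude_m``.
    tz_policy
        ``"utc"`` treats naive timestamps as UTC; a timezone name (e.g.
        ``"Europe/Madrid"``) treats naive timestamps as local time there and
        converts to UTC. Aware timestamps are always converted to UTC.

    Returns
    -------
    DataFrame sorted by ``(collar_id, timestamp)``, exact duplicates dropped
    (count logged), ``quality`` set to ``"observed"``.
    """
    raw = pd.read_csv(path, dtype={"collar_id": str, "herd_id": str})
    required = ["collar_id", "herd_id", "species", "timestamp", "lat", "lon"]
    for col in required:
        if col not in raw.columns:
            raise SchemaError(f"missing required column {col!r}")

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", utc=False, format="ISO8601")
    bad = ts.isna() & raw["timestamp"].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise RowError(f"unparsable timestamp {raw['timestamp'][bad.idxmax()]!r} "
                       f"at line {line}")
    if ts.dt.tz is None:
        if tz_policy.lower() == "utc":
            ts = ts.dt.tz_localize("UTC")
        else:
            ts = ts.dt.tz_localize(tz_policy, nonexistent="shift_forward",
                                   ambiguous=True)
    ts = ts.dt.tz_convert("UTC")

    lat = pd.to_numeric(raw["lat"], errors="coerce")
    lon = pd.to_numeric(raw["lon"], errors="coerce")
    out_of_range = (lat.abs() > 90) | (lon.abs() > 180) | lat.isna() | lon.isna()
    if out_of_range.any():
        idx = int(out_of_range.idxmax())
        raise RowError(f"invalid coordinates (lat={raw['lat'][idx]!r}, "
                       f"lon={raw['lon'][idx]!r}) at line {idx + 2}")

    fixes = pd.DataFrame({
        "collar_id": raw["collar_id"].astype(str),
        "herd_id": raw["herd_id"].astype(str),
        "species": raw["species"].map(normalize_species),
        "timestamp": ts,
        "lat": lat,
        "lon": lon,
        "altitude_m": pd.to_numeric(raw["altitude_m"], errors="coerce")
        if "altitude_m" in raw.columns else np.nan,
        "quality": "observed",
    })

    n0 = len(fixes)
    fixes = fixes.drop_duplicates(subset=["collar_id", "timestamp", "lat", "lon"])
    n_dup = n0 - len(fixes)
    if n_dup:
        logger.info("dropped %d duplicate fix rows", n_dup)
    # A collar cannot be in two places at one instant; keep the first record.
    fixes = fixes.drop_duplicates(subset=["collar_id", "timestamp"], keep="first")
    fixes = fixes.sort_values(["collar_id", "timestamp"], kind="mergesort")
    return fixes.reset_index(drop=True)[FIX_COLUMNS]


def write_fixes(fixes: pd.DataFrame, path) -> None:
    """Write a fix table back to CSV (ISO-8601 UTC timestamps)."""
    out = fixes.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False)


def read_weather(path) -> pd.DataFrame:
    """Read a daily weather table keyed by (date, station_id) and validate it."""
    wx = pd.read_csv(path, dtype={"station_id": str})
    for col in ["date", "station_id"]:
        if col not in wx.columns:
            raise SchemaError(f"missing required column {col!r}")
    wx["date"] = pd.to_datetime(wx["date"]).dt.date
    if {"t_min", "t_mean", "t_max"} <= set(wx.columns):
        ok = (wx["t_min"] <= wx["t_mean"]) & (wx["t_mean"] <= wx["t_max"])
        if not ok.all():
            raise RowError(f"t_min <= t_mean <= t_max violated at line "
                           f"{int((~ok).idxmax()) + 2}")
    if "rainfall" in wx.columns and (wx["rainfall"] < 0).any():
        raise RowError("negative rainfall")
    if "rh_mean" in wx.columns and not wx["rh_mean"].between(0, 100).all():
        raise RowError("rh_mean outside [0, 100]")
    return wx


def read_terrain_asc(path) -> TerrainGrid:
    """Read an ESRI ASCII grid (.asc) into a :class:`TerrainGrid`.

    The header's ``xllcorner/yllcorner`` are interpreted as the lon/lat of the
    lower-left *node* (``xllcenter/yllcenter`` accepted as synonyms here, the
    half-cell offset being negligible at test scales).
    """
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "xllcenter", "yllcenter", "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    arr = np.array(rows, dtype=float)
    # ESRI ASCII stores the northern row first; flip so row 0 is south.
    arr = arr[::-1]
    if "nodata_value" in header:
        arr[arr == header["nodata_value"]] = np.nan
        if np.isnan(arr).any():
            raise ValueError("terrain grid contains nodata cells")
    lat0 = header.get("yllcorner", header.get("yllcenter", 0.0))
    lon0 = header.get("xllcorner", header.get("xllcenter", 0.0))
    return TerrainGrid(origin_lat=lat0, origin_lon=lon0,
                       cell_size=header["cellsize"], elevation=arr)


def write_terrain_asc(grid: TerrainGrid, path) -> None:
    """Write a :class:`TerrainGrid` as an ESRI ASCII grid."""
    nrow, ncol = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncol}\nnrows {nrow}\n")
        fh.write(f"xllcorner {grid.origin_lon:.8f}\nyllcorner {grid.origin_lat:.8f}\n")
        fh.write(f"cellsize {grid.cell_size:.10f}\n")
        for row in grid.elevation[::-1]:
            fh.write(" ".join(f"{v:.2f}" for v in row) + "\n")


def read_features(path) -> dict[str, list]:
    """Read a GeoJSON feature layer into shapely geometries grouped by kind.

    Returns a mapping ``{kind: [geometry, ...]}`` where ``kind`` comes from the
    feature's ``properties["kind"]`` (falling back to ``"feature"``): points for
    water sources and buildings, linestrings for roads.
    """
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    layers: dict[str, list] = {}
    for feat in feats:
        kind = (feat.get("properties") or {}).get("kind", "feature")
        layers.setdefault(kind, []).append(shape(feat["geometry"]))
    return layers


def _bilinear(grid: TerrainGrid, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    nrow, ncol = grid.shape
    fi = (lat - grid.origin_lat) / grid.cell_size
    fj = (lon - grid.origin_lon) / grid.cell_size
    i0 = np.clip(np.floor(fi).astype(int), 0, nrow - 2)
    j0 = np.clip(np.floor(fj).astype(int), 0, ncol - 2)
    di = fi - i0
    dj = fj - j0
    z = grid.elevation
    return (z[i0, j0] * (1 - di) * (1 - dj) + z[i0 + 1, j0] * di * (1 - dj)
            + z[i0, j0 + 1] * (1 - di) * dj + z[i0 + 1, j0 + 1] * di * dj)


def sample_terrain(grid: TerrainGrid, lat, lon) -> pd.DataFrame:
    """Sample altitude and slope at geographic points.

    Altitude by bilinear interpolation between grid nodes; slope as the
    arctangent of the central-difference gradient magnitude, in degrees in
    [0, 90). Points outside the grid get NaN (flagged, not an error).
    """
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat_min, lat_max, lon_min, lon_max = grid.bounds()
    inside = ((lat >= lat_min) & (lat <= lat_max)
              & (lon >= lon_min) & (lon <= lon_max))

    alt = np.full(lat.shape, np.nan)
    slope = np.full(lat.shape, np.nan)
    if inside.any():
        alt[inside] = _bilinear(grid, lat[inside], lon[inside])
        # Metric node spacings for the gradient: one degree of latitude is
        # ~111.19 km; longitude shrinks by cos(lat).
        from .trajectory import EARTH_RADIUS_M
        dy = np.deg2rad(grid.cell_size) * EARTH_RADIUS_M
        mean_lat = np.deg2rad((lat_min + lat_max) / 2.0)
        dx = dy * np.cos(mean_lat)
        gi, gj = np.gradient(grid.elevation, dy, dx)
        grad_mag = np.hypot(gi, gj)
        slope_field = np.degrees(np.arctan(grad_mag))
        slope[inside] = _bilinear(
            TerrainGrid(grid.origin_lat, grid.origin_lon, grid.cell_size,
                        slope_field, grid.crs_tag),
            lat[inside], lon[inside])
    return pd.DataFrame({"altitude_m": alt, "slope_deg": slope})


def attach_terrain(fixes: pd.DataFrame, grid: TerrainGrid) -> pd.DataFrame:
    """Return fixes with ``altitude_m`` and ``slope_deg`` sampled from a grid."""
    sampled = sample_terrain(grid, fixes["lat"].to_numpy(), fixes["lon"].to_numpy())
    out = fixes.copy()
    out["altitude_m"] = sampled["altitude_m"].to_numpy()
    out["slope_deg"] = sampled["slope_deg"].to_numpy()
    return out
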