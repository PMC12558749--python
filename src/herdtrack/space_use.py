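"""Daily home range (95% minimum convex polygon) and herd dispersal.

The MCP follows the classic convention: compute the arithmetic-mean centroid
of a day's fixes, drop the points whose distance to the centroid exceeds the
requested percentile of those distances, and take the area of the convex hull
of the rest. The hull is built on a local tangent plane centered on the
centroid, so areas are in true square meters (reported in hectares).

Herd dispersal is the straight-line distance from each animal's synchronized
fix to the arithmetic centroid of all herd members present at that instant;
it is only defined at slots where at least two members have positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from .trajectory import DailyTrajectory, haversine_m, local_xy


@dataclass
class HomeRangeResult:
    collar_id: str
    date: object
    percent: float
    area_ha: float
    n_points_used: int
    polygon: np.ndarray        # (k, 2) array of (lat, lon) hull vertices
    degenerate: bool = False


def mcp_area(lat, lon, percent: float = 95.0,
             collar_id: str = "", date=None) -> HomeRangeResult:
    """Minimum-convex-polygon home range of one day's positions.

    Keeps points whose haversine distance to the mean-coordinate centroid is
    at or below the ``percent``-th percentile of those distances, then returns
    the convex-hull area of the kept points in hectares. Fewer than 5 distinct
    points give a degenerate result with area 0.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    pts = np.unique(np.column_stack([lat, lon]), axis=0)
    if len(lat) < 5 or len(pts) == 1:
        return HomeRangeResult(collar_id, date, percent, 0.0, len(pts),
                               pts, degenerate=True)
    clat, clon = float(lat.mean()), float(lon.mean())
    d = haversine_m(lat, lon, clat, clon)
    cutoff = np.percentile(d, percent)
    keep = d <= cutoff
    klat, klon = lat[keep], lon[keep]
    x, y = local_xy(klat, klon, clat, clon)
    hull = MultiPoint(np.column_stack([x, y])).convex_hull
    area_ha = hull.area / 10_000.0
    if hull.geom_type == "Polygon":
        hx, hy = np.asarray(hull.exterior.coords[:-1]).T
        vlat = clat + np.degrees(hy / 6_371_000.0)
        vlon = clon + np.degrees(hx / (6_371_000.0 * np.cos(np.radians(clat))))
        poly = np.column_stack([vlat, vlon])
    else:  # collinear or coincident kept points: zero-area hull
        poly = np.column_stack([klat, klon])
    return HomeRangeResult(collar_id, date, percent, float(area_ha),
                           int(keep.sum()), poly, degenerate=False)


def daily_home_ranges(trajectories: list[DailyTrajectory],
                      percent: float = 95.0,
                      exclude_imputed: bool = True) -> pd.DataFrame:
    """95% MCP per collar-day from standardized trajectories.

    Edge-held (imputed) slots are excluded by default: a held position repeats
    one coordinate many times and would fabricate a zero-movement cluster.
    """
    rows = []
    for t in trajectories:
        use = ~t.imputed if exclude_imputed else np.ones(len(t.lat), bool)
        res = mcp_area(t.lat[use], t.lon[use], percent,
                       collar_id=t.collar_id, date=t.date)
        rows.append({"collar_id": t.collar_id, "herd_id": t.herd_id,
                     "species": t.species, "date": t.date,
                     "percent": percent, "area_ha": res.area_ha,
                     "n_points_used": res.n_points_used,
                     "degenerate": res.degenerate})
    return pd.DataFrame(rows)


def herd_centroid(lat, lon) -> tuple[float, float]:
    """Arithmetic-mean centroid of member positions at one synchronized slot."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if len(lat) < 2:
        raise ValueError("herd centroid requires at least 2 animals")
    return float(lat.mean()), float(lon.mean())


def dispersal(trajectories: list[DailyTrajectory],
              exclude_imputed: bool = True) -> pd.DataFrame:
    """Per-animal distance to the synchronized herd centroid, per 30-min slot.

    Positions must already be on the standardized grid (the synchronization
    the centroid needs). Slots where a herd has fewer than two members with
    usable positions are skipped.
    """
    frames = []
    for t in trajectories:
        use = ~t.imputed if exclude_imputed else np.ones(len(t.lat), bool)
        if not use.any():
            continue
        times = t.slot_times()[use]
        frames.append(pd.DataFrame({
            "herd_id": t.herd_id, "collar_id": t.collar_id,
            "species": t.species, "slot_time": times,
            "lat": t.lat[use], "lon": t.lon[use]}))
    if not frames:
        return pd.DataFrame(columns=["herd_id", "slot_time", "collar_id",
                                     "species", "dist_to_centroid_m",
                                     "n_animals"])
    table = pd.concat(frames, ignore_index=True)
    grp = table.groupby(["herd_id", "slot_time"])
    n = grp["collar_id"].transform("size")
    clat = grp["lat"].transform("mean")
    clon = grp["lon"].transform("mean")
    table["n_animals"] = n
    table["dist_to_centroid_m"] = haversine_m(
        table["lat"].to_numpy(), table["lon"].to_numpy(),
        clat.to_numpy(), clon.to_numpy())
    table = table[table["n_animals"] >= 2]
    return table[["herd_id", "slot_time", "collar_id", "species",
                  "dist_to_centroid_m", "n_animals"]].reset_index(drop=True)
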