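"""Standardized daily trajectories.

A cleaned collar-day is resampled onto the 48-slot grid (00:00, 00:30, ...,
23:30 UTC), smoothed with a Savitzky-Golay filter (order 3, window 5, applied
to the latitude and longitude series independently), and summarized into the
movement indicators: step lengths, velocities, daily path length and net
displacement. All distances are great-circle (haversine) on a sphere of
radius 6,371,000 m; interpolation and smoothing act on degrees directly,
which is accurate far from the poles and the antimeridian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

EARTH_RADIUS_M = 6_371_000.0

#: Number of standardized 30-min slots per day.
SLOTS_PER_DAY = 48
SLOT_SECONDS = 1800.0


@dataclass
class SmoothingConfig:
    polyorder: int = 3
    window: int = 5

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if self.polyorder >= self.window:
            raise ValueError("polyorder must be < window")


@dataclass
class DailyTrajectory:
    """One collar-day on the standardized 30-min grid."""

    collar_id: str
    date: object
    lat: np.ndarray            # 48 slots
    lon: np.ndarray            # 48 slots
    imputed: np.ndarray        # bool per slot: edge-held, not interpolated
    herd_id: str = ""
    species: str = ""

    def slot_times(self) -> pd.DatetimeIndex:
        start = pd.Timestamp(self.date, tz="UTC")
        return pd.date_range(start, periods=SLOTS_PER_DAY, freq="30min")

    @property
    def step_lengths_m(self) -> np.ndarray:
        return haversine_m(self.lat[:-1], self.lon[:-1], self.lat[1:], self.lon[1:])

    @property
    def velocities_ms(self) -> np.ndarray:
        return self.step_lengths_m / SLOT_SECONDS

    @property
    def path_km(self) -> float:
        return float(self.step_lengths_m.sum()) / 1000.0

    def net_displacement_km(self, next_day: "DailyTrajectory | None" = None) -> float:
        """Straight-line km from this day's 00:00 slot to the next day's 00:00
        slot; falls back to first-to-last slot of the day when no next day."""
        if next_day is not None:
            return float(haversine_m(self.lat[0], self.lon[0],
                                     next_day.lat[0], next_day.lon[0])) / 1000.0
        return float(haversine_m(self.lat[0], self.lon[0],
                                 self.lat[-1], self.lon[-1])) / 1000.0


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in meters between WGS84 points (vectorized)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def local_xy(lat, lon, lat0, lon0):
    """Project points to a local tangent plane centered at (lat0, lon0).

    Equirectangular: x east, y north, meters. Distortion is below 0.1% at the
    <=10 km extents of a collar-day, which is the only scale it is used at.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    x = np.radians(lon - lon0) * EARTH_RADIUS_M * np.cos(np.radians(lat0))
    y = np.radians(lat - lat0) * EARTH_RADIUS_M
    return x, y


def resample_day(batch) -> DailyTrajectory:
    """Resample a QC-passing day onto the 48-slot grid.

    Grid instants inside the observed span are linearly interpolated in lat and
    lon between the bracketing fixes; instants before the first or after the
    last fix hold the nearest observed position and are flagged imputed.
    """
    fixes = batch.fixes
    if len(fixes) < 2:
        raise ValueError("cannot interpolate a day with fewer than 2 fixes")
    t0 = pd.Timestamp(batch.date, tz="UTC")
    obs_s = (fixes["timestamp"] - t0).dt.total_seconds().to_numpy()
    grid_s = np.arange(SLOTS_PER_DAY) * SLOT_SECONDS
    lat = np.interp(grid_s, obs_s, fixes["lat"].to_numpy())
    lon = np.interp(grid_s, obs_s, fixes["lon"].to_numpy())
    imputed = (grid_s < obs_s[0]) | (grid_s > obs_s[-1])
    herd = str(fixes["herd_id"].iloc[0]) if "herd_id" in fixes else ""
    spp = str(fixes["species"].iloc[0]) if "species" in fixes else ""
    return DailyTrajectory(collar_id=batch.collar_id, date=batch.date,
                           lat=lat, lon=lon, imputed=imputed,
                           herd_id=herd, species=spp)


def smooth_savgol(series: np.ndarray, cfg: SmoothingConfig | None = None
                  ) -> np.ndarray:
    """Savitzky-Golay smoothing of one coordinate series.

    Interior values are replaced by the central value of the degree-`polyorder`
    least-squares fit over the moving window; the first and last half-windows
    are filled from a polynomial of the same order fitted to the edge-most
    `window` points (one-sided fit), so the series keeps its full length.
    """
    cfg = cfg or SmoothingConfig()
    series = np.asarray(series, dtype=float)
    if len(series) < cfg.window:
        raise ValueError("series shorter than the smoothing window")
    return savgol_filter(series, window_length=cfg.window,
                         polyorder=cfg.polyorder, mode="interp")


def smooth_trajectory(traj: DailyTrajectory,
                      cfg: SmoothingConfig | None = None) -> DailyTrajectory:
    """Smooth a trajectory's latitude and longitude series independently."""
    return DailyTrajectory(collar_id=traj.collar_id, date=traj.date,
                           lat=smooth_savgol(traj.lat, cfg),
                           lon=smooth_savgol(traj.lon, cfg),
                           imputed=traj.imputed.copy(),
                           herd_id=traj.herd_id, species=traj.species)


def movement_indicators(traj: DailyTrajectory,
                        next_day: DailyTrajectory | None = None) -> dict:
    """Movement indicators of one (smoothed) daily trajectory.

    ``path_km`` is the summed step length (the headline daily distance);
    ``net_displacement_km`` the midnight-to-midnight straight line.
    """
    return {
        "collar_id": traj.collar_id,
        "date": traj.date,
        "step_lengths_m": traj.step_lengths_m,
        "velocities_ms": traj.velocities_ms,
        "path_km": traj.path_km,
        "net_displacement_km": traj.net_displacement_km(next_day),
    }


def build_daily_trajectories(kept_fixes: pd.DataFrame,
                             smoothing: SmoothingConfig | None = None,
                             smooth: bool = True) -> list[DailyTrajectory]:
    """Resample (and by default smooth) every cleaned collar-day."""
    from .cleaning import partition_days
    out = []
    for batch in partition_days(kept_fixes):
        if len(batch) < 2:
            continue
        traj = resample_day(batch)
        if smooth:
            traj = smooth_trajectory(traj, smoothing)
        out.append(traj)
    return out


def daily_metrics_table(trajectories: list[DailyTrajectory]) -> pd.DataFrame:
    """One row per collar-day: path, net displacement, velocity summaries."""
    by_collar: dict[str, list[DailyTrajectory]] = {}
    for t in trajectories:
        by_collar.setdefault(t.collar_id, []).append(t)
    rows = []
    for collar, days in by_collar.items():
        days.sort(key=lambda t: t.date)
        for i, t in enumerate(days):
            nxt = days[i + 1] if (i + 1 < len(days)
                                  and (days[i + 1].date - t.date).days == 1) else None
            v = t.velocities_ms
            rows.append({"collar_id": collar, "herd_id": t.herd_id,
                         "species": t.species, "date": t.date,
                         "path_km": t.path_km,
                         "net_displacement_km": t.net_displacement_km(nxt),
                         "mean_velocity_ms": float(v.mean()),
                         "max_velocity_ms": float(v.max()),
                         "n_imputed_slots": int(t.imputed.sum())})
    return pd.DataFrame(rows)
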