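"""Solar geometry and day/twilight/night partitioning of daily movement.

The sun's elevation is computed with the standard NOAA low-accuracy ephemeris
approximation (fractional-year Fourier series for declination and the equation
of time), good to well under 0.5 degrees — ample for 30-min slots. Daylight is
bounded at -0.833 degrees (refraction plus the solar radius, the civil
sunrise/sunset convention); twilight extends down to the nautical boundary at
-12 degrees; anything lower is night. Each 30-min step of a standardized
trajectory is assigned to the diel class of its midpoint instant at the step's
midpoint position, and a day's activity is partitioned as each class's share
of the total distance traveled during the 24 h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import DailyTrajectory


@dataclass
class SolarConfig:
    sunrise_elevation_deg: float = -0.833
    nautical_elevation_deg: float = -12.0

    def __post_init__(self) -> None:
        if self.nautical_elevation_deg >= self.sunrise_elevation_deg:
            raise ValueError("nautical boundary must lie below the sunrise "
                             "boundary")


def solar_elevation(lat, lon, when) -> np.ndarray:
    """Sun elevation above the horizon, degrees (NOAA approximation).

    ``when`` is a UTC timestamp or DatetimeIndex; ``lat``/``lon`` in WGS84
    degrees (broadcastable against ``when``). No refraction correction is
    applied to the elevation itself; the class boundaries absorb it.
    """
    times = pd.DatetimeIndex(np.atleast_1d(pd.to_datetime(when, utc=True)))
    doy = times.dayofyear.to_numpy()
    hours = (times.hour + times.minute / 60.0 + times.second / 3600.0).to_numpy()

    gamma = 2.0 * np.pi / 365.0 * (doy - 1 + (hours - 12.0) / 24.0)
    eqtime = 229.18 * (0.000075 + 0.001868 * np.cos(gamma)
                       - 0.032077 * np.sin(gamma)
                       - 0.014615 * np.cos(2 * gamma)
                       - 0.040849 * np.sin(2 * gamma))
    decl = (0.006918 - 0.399912 * np.cos(gamma) + 0.070257 * np.sin(gamma)
            - 0.006758 * np.cos(2 * gamma) + 0.000907 * np.sin(2 * gamma)
            - 0.002697 * np.cos(3 * gamma) + 0.00148 * np.sin(3 * gamma))

    lat_r = np.radians(np.asarray(lat, dtype=float))
    lon_d = np.asarray(lon, dtype=float)
    # True solar time in minutes; hour angle in degrees (solar noon = 0).
    tst = hours * 60.0 + eqtime + 4.0 * lon_d
    ha = np.radians(tst / 4.0 - 180.0)
    cos_zen = (np.sin(lat_r) * np.sin(decl)
               + np.cos(lat_r) * np.cos(decl) * np.cos(ha))
    elev = 90.0 - np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0)))
    if np.isscalar(lat) and len(times) == 1:
        return float(elev[0])
    return elev


def diel_class(elevation_deg, cfg: SolarConfig | None = None) -> np.ndarray:
    """Map solar elevations to day / twilight / night.

    ``elev > sunrise`` -> day; ``nautical < elev <= sunrise`` -> twilight;
    ``elev <= nautical`` -> night. Covers every elevation exactly once.
    """
    cfg = cfg or SolarConfig()
    elev = np.asarray(elevation_deg, dtype=float)
    out = np.where(elev > cfg.sunrise_elevation_deg, "day",
                   np.where(elev > cfg.nautical_elevation_deg,
                            "twilight", "night"))
    if np.isscalar(elevation_deg):
        return str(out)
    return out


def activity_partition(traj: DailyTrajectory,
                       cfg: SolarConfig | None = None) -> dict:
    """Partition one day's traveled distance into day/twilight/night percent.

    Each step's length accrues to the diel class of the step's midpoint
    instant, evaluated at the step's midpoint position. Fractions sum to 100%
    unless the day has zero total path (flagged undefined).
    """
    cfg = cfg or SolarConfig()
    steps = traj.step_lengths_m
    times = traj.slot_times()
    mid_times = times[:-1] + pd.Timedelta(minutes=15)
    mid_lat = 0.5 * (traj.lat[:-1] + traj.lat[1:])
    mid_lon = 0.5 * (traj.lon[:-1] + traj.lon[1:])
    elev = solar_elevation(mid_lat, mid_lon, mid_times)
    classes = diel_class(elev, cfg)
    total = steps.sum()
    out = {"collar_id": traj.collar_id, "date": traj.date,
           "defined": bool(total > 0)}
    for cls in ("day", "twilight", "night"):
        part = steps[classes == cls].sum()
        out[f"frac_{cls}"] = float(part / total * 100.0) if total > 0 else np.nan
    return out


def diel_table(trajectories: list[DailyTrajectory],
               cfg: SolarConfig | None = None) -> pd.DataFrame:
    """Activity partition rows for every trajectory."""
    return pd.DataFrame([activity_partition(t, cfg) for t in trajectories])
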