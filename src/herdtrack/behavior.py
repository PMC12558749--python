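"""Velocity-based behavior classification and behavior profiles.

Each 30-min step velocity is classified as resting, grazing, or walking using
the 57.5th and 97.5th percentiles of the velocity distribution as thresholds —
the split under which cattle spend 57.5% of their time resting (including
rumination), 40% grazing and 2.5% walking. Because species differ in speed and
terrain steepness slows movement, thresholds are fitted separately per
(species, slope-bin) stratum, with a species-pooled fallback for sparse strata.

Quantiles use the linear-interpolation definition between order statistics;
a velocity exactly at a threshold takes the lower-activity state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.ops import transform as shapely_transform
from shapely.geometry import Point

from .trajectory import DailyTrajectory, local_xy

logger = logging.getLogger(__name__)

STATES = ("resting", "grazing", "walking")

#: Default slope-bin edges in degrees; bins are [0,10), [10,20), [20,90).
DEFAULT_SLOPE_EDGES = (0.0, 10.0, 20.0, 90.0)

#: Minimum velocities per stratum before falling back to species-pooled fit.
MIN_STRATUM_N = 100


@dataclass
class ThresholdSet:
    """Fitted velocity cut points per (species, slope_bin) stratum.

    ``strata[(species, bin_index)] = (v_low, v_high)`` in m/s; ``bin_index``
    ``None`` holds the species-pooled fallback used for sparse strata and for
    steps with unknown slope.
    """

    strata: dict
    percentiles: tuple = (57.5, 97.5)
    slope_bin_edges: tuple = DEFAULT_SLOPE_EDGES

    def __post_init__(self) -> None:
        lo, hi = self.percentiles
        if not (0 < lo < hi < 100):
            raise ValueError("percentiles must be strictly increasing in (0, 100)")
        for key, (v_low, v_high) in self.strata.items():
            if v_low > v_high:
                raise ValueError(f"v_low > v_high in stratum {key}")

    def slope_bin(self, slope_deg) -> np.ndarray:
        """Bin index for slope values; NaN slopes map to -1 (pooled)."""
        slope = np.asarray(slope_deg, dtype=float)
        edges = np.asarray(self.slope_bin_edges)
        idx = np.digitize(slope, edges[1:-1])
        idx = np.where(np.isnan(slope), -1, idx)
        return idx.astype(int)

    def lookup(self, species: str, bin_index: int) -> tuple:
        if bin_index >= 0 and (species, bin_index) in self.strata:
            return self.strata[(species, bin_index)]
        if (species, None) in self.strata:
            return self.strata[(species, None)]
        raise KeyError(f"no thresholds for species {species!r}")


def fit_thresholds(velocities: pd.DataFrame,
                   percentiles: tuple = (57.5, 97.5),
                   slope_bin_edges: tuple = DEFAULT_SLOPE_EDGES,
                   min_stratum_n: int = MIN_STRATUM_N) -> ThresholdSet:
    """Fit per-stratum velocity thresholds at the calibration percentiles.

    Parameters
    ----------
    velocities
        DataFrame with columns ``velocity_ms``, ``species`` and (optionally)
        ``slope_deg``. Slope may be all-NaN, in which case only species-pooled
        thresholds are fitted.
    percentiles
        The two cut percentiles (defaults 57.5 and 97.5).
    slope_bin_edges
        Slope-bin edges in degrees.
    min_stratum_n
        Strata with fewer velocities fall back to the species-pooled
        thresholds (logged).
    """
    if velocities.empty:
        raise ValueError("no velocities to fit thresholds on")
    v = velocities["velocity_ms"].to_numpy(dtype=float)
    species = velocities["species"].to_numpy()
    slope = (velocities["slope_deg"].to_numpy(dtype=float)
             if "slope_deg" in velocities.columns
             else np.full(len(velocities), np.nan))

    dummy = ThresholdSet(strata={}, percentiles=percentiles,
                         slope_bin_edges=slope_bin_edges)
    bins = dummy.slope_bin(slope)

    strata: dict = {}
    for sp in np.unique(species):
        mask_sp = species == sp
        pooled = tuple(np.percentile(v[mask_sp], percentiles))
        strata[(sp, None)] = pooled
        for b in range(len(slope_bin_edges) - 1):
            mask = mask_sp & (bins == b)
            n = int(mask.sum())
            if n == 0:
                continue
            if n < min_stratum_n:
                logger.info("stratum (%s, slope bin %d) has %d < %d velocities; "
                            "using species-pooled thresholds", sp, b, n,
                            min_stratum_n)
                continue
            strata[(sp, b)] = tuple(np.percentile(v[mask], percentiles))
    return ThresholdSet(strata=strata, percentiles=percentiles,
                        slope_bin_edges=slope_bin_edges)


def classify(velocity_ms, species, slope_deg, thresholds: ThresholdSet):
    """Classify velocities into resting / grazing / walking (vectorized).

    ``v <= v_low`` -> resting, ``v_low < v <= v_high`` -> grazing,
    ``v > v_high`` -> walking.
    """
    v = np.atleast_1d(np.asarray(velocity_ms, dtype=float))
    species_arr = np.broadcast_to(np.atleast_1d(species), v.shape)
    slope_arr = np.broadcast_to(np.atleast_1d(np.asarray(slope_deg, dtype=float)),
                                v.shape)
    bins = thresholds.slope_bin(slope_arr)
    out = np.empty(v.shape, dtype=object)
    for sp in np.unique(species_arr):
        for b in np.unique(bins):
            mask = (species_arr == sp) & (bins == b)
            if not mask.any():
                continue
            v_low, v_high = thresholds.lookup(str(sp), int(b))
            states = np.where(v[mask] <= v_low, "resting",
                              np.where(v[mask] <= v_high, "grazing", "walking"))
            out[mask] = states
    if np.isscalar(velocity_ms):
        return str(out[0])
    return out.astype(str)


def label_steps(trajectories: list[DailyTrajectory],
                terrain=None,
                include_imputed: bool = False) -> pd.DataFrame:
    """Build the per-step label table from smoothed daily trajectories.

    Each of the 47 steps of a day yields one row at the step's *end* slot,
    carrying the step velocity and the end-slot position. Steps touching an
    edge-held (imputed) slot are excluded unless ``include_imputed``. If a
    terrain grid is given, slope is sampled at the step position.
    """
    rows = []
    for t in trajectories:
        times = t.slot_times()
        v = t.velocities_ms
        step_ok = ~(t.imputed[:-1] | t.imputed[1:])
        for i in range(len(v)):
            if not include_imputed and not step_ok[i]:
                continue
            rows.append({"collar_id": t.collar_id, "herd_id": t.herd_id,
                         "species": t.species, "date": t.date,
                         "slot_time": times[i + 1],
                         "lat": t.lat[i + 1], "lon": t.lon[i + 1],
                         "velocity_ms": v[i]})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    if terrain is not None:
        from .io_ingest import sample_terrain
        sampled = sample_terrain(terrain, table["lat"].to_numpy(),
                                 table["lon"].to_numpy())
        table["slope_deg"] = sampled["slope_deg"].to_numpy()
        table["altitude_m"] = sampled["altitude_m"].to_numpy()
    else:
        table["slope_deg"] = np.nan
    return table


def classify_table(table: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Attach a ``state`` column to a step-label table."""
    out = table.copy()
    out["state"] = classify(table["velocity_ms"].to_numpy(),
                            table["species"].to_numpy(),
                            table["slope_deg"].to_numpy(), thresholds)
    return out


def diel_behavior_profile(labels: pd.DataFrame) -> pd.DataFrame:
    """Per time-of-day proportions of each behavior state.

    Returns one row per 30-min slot-of-day present in the labels, with columns
    ``slot_of_day`` (minutes since midnight UTC), one proportion column per
    state and ``n``; proportions sum to 1 per slot.
    """
    slot = labels["slot_time"].dt.hour * 60 + labels["slot_time"].dt.minute
    counts = (labels.assign(slot_of_day=slot)
              .groupby("slot_of_day")["state"].value_counts().unstack(fill_value=0)
              .reindex(columns=list(STATES), fill_value=0))
    n = counts.sum(axis=1)
    prof = counts.div(n, axis=0)
    prof["n"] = n
    return prof.reset_index()


def distance_to_features(lat, lon, geometries) -> np.ndarray:
    """Haversine-consistent distance (m) from points to the nearest feature.

    Points and features are projected onto one local tangent plane centered on
    the point cloud (valid at study extents); distances to LineStrings are true
    point-to-segment distances via shapely.
    """
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat0, lon0 = float(lat.mean()), float(lon.mean())

    def proj(x, y, z=None):  # shapely transform signature: lon, lat
        px, py = local_xy(y, x, lat0, lon0)
        return px, py

    projected = [shapely_transform(proj, g) for g in geometries]
    x, y = local_xy(lat, lon, lat0, lon0)
    dists = np.empty(len(lat))
    for i in range(len(lat)):
        p = Point(x[i], y[i])
        dists[i] = min(g.distance(p) for g in projected)
    return dists


def proximity_profile(labels: pd.DataFrame, geometries,
                      bin_edges) -> pd.DataFrame:
    """State proportions by distance-to-nearest-feature bin.

    ``bin_edges`` in meters define half-open bins ``[e0, e1), [e1, e2), ...``.
    Empty bins are emitted with ``n = 0`` and NaN proportions (flagged via the
    ``defined`` column).
    """
    if not geometries:
        raise ValueError("feature layer is empty")
    edges = np.asarray(bin_edges, dtype=float)
    d = distance_to_features(labels["lat"].to_numpy(),
                             labels["lon"].to_numpy(), geometries)
    bin_idx = np.digitize(d, edges) - 1
    in_range = (bin_idx >= 0) & (bin_idx < len(edges) - 1)
    sub = labels.loc[in_range].assign(dist_bin=bin_idx[in_range])
    counts = (sub.groupby("dist_bin")["state"].value_counts().unstack(fill_value=0)
              .reindex(index=range(len(edges) - 1), columns=list(STATES),
                       fill_value=0))
    n = counts.sum(axis=1)
    prof = counts.div(n.replace(0, np.nan), axis=0)
    prof["n"] = n
    prof["defined"] = n > 0
    prof.insert(0, "bin_low_m", edges[:-1])
    prof.insert(1, "bin_high_m", edges[1:])
    return prof.reset_index(drop=True)
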