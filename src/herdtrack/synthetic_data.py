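"""Seedable herd simulator emulating collar data from mountain pastures.

The generator is the ground truth every pipeline stage is tested against. It
produces three-state (resting / grazing / walking) correlated-random-walk
tracks for herds of cows, horses and sheep on a synthetic mountain terrain:

* behavior states switch by a time-of-day-dependent Markov chain whose
  stationary grazing probability has two configurable diel peaks, with a
  time-averaged state mix near the 57.5 / 40 / 2.5 resting/grazing/walking
  split the classification thresholds assume;
* step lengths are the state's characteristic speed over the 30-min slot with
  multiplicative lognormal noise (unit-mean multiplier, so realized state
  speeds average to the configured means);
* headings are correlated (wrapped-normal turning) and each animal is pulled
  toward its herd's centroid (cohesion) and weakly toward the herd's camp,
  which drifts with a monthly target altitude along the terrain's
  south-to-north elevation ramp;
* transmission emulates a lossy low-power radio link: independent per-fix
  message loss plus occasional multi-hour burst outages.

Species defaults order daily travel ovine > bovine > equine and cohesion
ovine > equine > bovine (so dispersal orders bovine > equine > ovine); they
are configuration, not claims about real herds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io_ingest import FIX_COLUMNS, TerrainGrid, sample_terrain
from .trajectory import EARTH_RADIUS_M, SLOTS_PER_DAY, SLOT_SECONDS, local_xy

STATE_INDEX = {"resting": 0, "grazing": 1, "walking": 2}
STATE_NAMES = ("resting", "grazing", "walking")


@dataclass
class SpeciesParams:
    """Movement parameters of one species (speeds in m/s)."""

    resting_speed: float
    grazing_speed: float
    walking_speed: float
    speed_log_sd: float = 0.35
    cohesion_strength: float = 0.02   # per-slot pull toward herd centroid, [0,1]

    def __post_init__(self) -> None:
        if not (0 <= self.resting_speed < self.grazing_speed
                < self.walking_speed):
            raise ValueError("state speeds must be ordered "
                             "resting < grazing < walking")
        if not 0 <= self.cohesion_strength < 1:
            raise ValueError("cohesion_strength must be in [0, 1)")

    def speed(self, state_idx: int) -> float:
        return (self.resting_speed, self.grazing_speed,
                self.walking_speed)[state_idx]


#: Default species parameterization (see module docstring for the orderings).
DEFAULT_SPECIES_PARAMS = {
    "bovine": SpeciesParams(0.005, 0.030, 0.150, cohesion_strength=0.008),
    "equine": SpeciesParams(0.005, 0.026, 0.130, cohesion_strength=0.015),
    "ovine": SpeciesParams(0.006, 0.055, 0.250, cohesion_strength=0.180),
}


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic herds.

    Two herds per species, ten collars per herd, 30 days of 30-min fixes from
    June 1st — a desk-scale slice of a May-October mountain grazing season.
    Message loss of 0.30 reflects a link that delivers roughly two thirds of
    the nominal 48 fixes per day; burst outages add the occasional multi-hour
    gap that the day-level QC exists to catch.
    """

    species_by_herd: tuple = ("bovine", "bovine", "equine", "equine",
                              "ovine", "ovine")
    animals_per_herd: int = 10
    days: int = 30
    start_date: Date = Date(2022, 6, 1)
    species_params: dict = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_PARAMS))
    diel_peaks: tuple = (7.0, 17.0)   # grazing peak hours, UTC
    diel_peak_width_h: float = 1.5
    grazing_base: float = 0.30
    grazing_peak_amp: float = 0.32
    walking_prob: float = 0.025
    state_persistence: float = 0.50
    heading_sd_deg: float = 60.0
    burn_in_days: int = 3
    camp_attraction: float = 0.005
    msg_loss_rate: float = 0.30
    burst_gap_rate: float = 0.15      # per collar-day probability of an outage
    burst_hours: tuple = (6.0, 18.0)
    altitude_target_by_month: dict = field(default_factory=lambda: {
        5: 1500.0, 6: 1700.0, 7: 1900.0, 8: 1900.0, 9: 1700.0, 10: 1500.0})
    camp_drift_per_day: float = 0.15  # fraction of the gap to target closed daily
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.msg_loss_rate < 1:
            raise ValueError("msg_loss_rate must be in [0, 1)")
        for sp in self.species_by_herd:
            if sp not in self.species_params:
                raise ValueError(f"no parameters for species {sp!r}")

    @property
    def n_herds(self) -> int:
        return len(self.species_by_herd)

    def state_marginals(self, hour: float) -> np.ndarray:
        """Target state distribution (resting, grazing, walking) at an hour.

        Grazing probability is a baseline plus two Gaussian bumps at the
        configured peak hours (wrapped on the 24-h circle); walking is a small
        constant; resting takes the remainder.
        """
        g = self.grazing_base
        for peak in self.diel_peaks:
            dh = (hour - peak + 12.0) % 24.0 - 12.0
            g += self.grazing_peak_amp * np.exp(
                -0.5 * (dh / self.diel_peak_width_h) ** 2)
        w = self.walking_prob
        r = 1.0 - g - w
        if r < 0:
            raise ValueError("grazing peaks too large: resting probability "
                             "would be negative")
        return np.array([r, g, w])

    def transition_matrix(self, hour: float) -> np.ndarray:
        """Row-stochastic 3x3 state transition matrix for a time of day."""
        pi = self.state_marginals(hour)
        p = self.state_persistence
        return p * np.eye(3) + (1 - p) * np.ones((3, 1)) * pi


# Geographic frame of the synthetic study area (a Pyrenean-style block).
AREA_LAT_MIN, AREA_LAT_MAX = 42.30, 42.70
AREA_LON_MIN, AREA_LON_MAX = 1.00, 1.40
TERRAIN_ALT_MIN, TERRAIN_ALT_MAX = 900.0, 2900.0


def simulate_terrain(seed: int = 0, n: int = 81, cell_size: float = 0.005,
                     smoothness: float = 6.0,
                     noise_amp: float = 150.0) -> TerrainGrid:
    """Smooth pseudo-random mountain terrain, 900-2,900 m.

    A south-to-north elevation ramp (valley floor to high pasture) plus
    Gaussian-smoothed noise; ``smoothness`` is the Gaussian sigma in cells and
    sets the spatial correlation length. Reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    ramp = np.linspace(TERRAIN_ALT_MIN + noise_amp,
                       TERRAIN_ALT_MAX - noise_amp, n)[:, None]
    noise = gaussian_filter(rng.standard_normal((n, n)), smoothness,
                            mode="reflect")
    sd = noise.std()
    if sd > 0:
        noise = noise / sd * noise_amp
    elev = np.clip(ramp + noise, TERRAIN_ALT_MIN, TERRAIN_ALT_MAX)
    return TerrainGrid(origin_lat=AREA_LAT_MIN, origin_lon=AREA_LON_MIN,
                       cell_size=cell_size, elevation=elev)


def _camp_lat_for_altitude(target_m: float) -> float:
    """Latitude on the terrain ramp whose ramp altitude matches a target."""
    frac = (target_m - TERRAIN_ALT_MIN) / (TERRAIN_ALT_MAX - TERRAIN_ALT_MIN)
    frac = float(np.clip(frac, 0.05, 0.95))
    return AREA_LAT_MIN + frac * (AREA_LAT_MAX - AREA_LAT_MIN)


def simulate_herds(cfg: SimConfig | None = None,
                   terrain: TerrainGrid | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate truth tracks and transmitted fixes for all herds.

    Returns ``(truth, fixes)``: truth has one row per collar per 30-min slot
    with the behavioral state, position and a ``transmitted`` flag; fixes is
    the transmitted subset in the canonical collar-CSV layout (a valid
    ``io_ingest`` table). If a terrain grid is given, fixes carry sampled
    altitudes.
    """
    cfg = cfg or SimConfig()
    root = np.random.SeedSequence(cfg.seed)
    herd_seeds = root.spawn(cfg.n_herds)

    # Burn-in lets the herd-spread process reach its stationary regime before
    # any output slot; the burn-in slots are simulated and discarded.
    n_burn = cfg.burn_in_days * SLOTS_PER_DAY
    n_slots = n_burn + cfg.days * SLOTS_PER_DAY
    start = pd.Timestamp(cfg.start_date, tz="UTC")
    slot_times = pd.date_range(start - pd.Timedelta(days=cfg.burn_in_days),
                               periods=n_slots, freq="30min")
    hours = ((np.arange(n_slots) % SLOTS_PER_DAY) * 0.5)
    months = slot_times.month.to_numpy()

    # Pre-computed per-slot target marginals (same for all herds).
    marginals = np.stack([cfg.state_marginals(h) for h in hours])

    frames = []
    for h_idx, sp in enumerate(cfg.species_by_herd):
        rng = np.random.default_rng(herd_seeds[h_idx])
        params = cfg.species_params[sp]
        n_animals = cfg.animals_per_herd
        herd_id = f"H{h_idx + 1:02d}"

        # Camp starts at the latitude matching the starting month's target
        # altitude, with herds spread in longitude.
        month0 = cfg.start_date.month
        target0 = cfg.altitude_target_by_month.get(month0, 1700.0)
        camp_lat0 = _camp_lat_for_altitude(target0)
        camp_lon0 = (AREA_LON_MIN + (h_idx + 1)
                     * (AREA_LON_MAX - AREA_LON_MIN) / (cfg.n_herds + 1))
        lat_ref, lon_ref = camp_lat0, camp_lon0
        m_per_deg_lat = np.radians(1.0) * EARTH_RADIUS_M

        camp = np.array([0.0, 0.0])           # tangent-plane meters
        xy = rng.normal(0.0, 150.0, size=(n_animals, 2))
        heading = rng.uniform(0.0, 2 * np.pi, size=n_animals)
        state = rng.choice(3, size=n_animals, p=marginals[0])

        states = np.empty((n_slots, n_animals), dtype=np.int8)
        lats = np.empty((n_slots, n_animals))
        lons = np.empty((n_slots, n_animals))
        speed_means = np.array([params.speed(s) for s in range(3)])
        sd = params.speed_log_sd
        persist = cfg.state_persistence
        head_sd = np.radians(cfg.heading_sd_deg)

        for t in range(n_slots):
            if t > 0:
                resample = rng.random(n_animals) >= persist
                n_new = int(resample.sum())
                if n_new:
                    state[resample] = rng.choice(3, size=n_new, p=marginals[t])
            states[t] = state

            # Daily camp drift toward the month's target altitude.
            if t % SLOTS_PER_DAY == 0 and t > 0:
                target = cfg.altitude_target_by_month.get(int(months[t]), 1700.0)
                target_y = (_camp_lat_for_altitude(target) - lat_ref) * m_per_deg_lat
                camp[1] += cfg.camp_drift_per_day * (target_y - camp[1])

            # Unit-mean lognormal speed multiplier keeps realized state-speed
            # means at the configured values.
            mult = np.exp(rng.normal(-0.5 * sd * sd, sd, size=n_animals))
            step = speed_means[state] * mult * SLOT_SECONDS
            heading = heading + rng.normal(0.0, head_sd, size=n_animals)
            move = step[:, None] * np.column_stack([np.sin(heading),
                                                    np.cos(heading)])
            centroid = xy.mean(axis=0)
            xy = (xy + move
                  + params.cohesion_strength * (centroid - xy)
                  + cfg.camp_attraction * (camp - xy))
            lats[t] = lat_ref + xy[:, 1] / m_per_deg_lat
            lons[t] = lon_ref + xy[:, 0] / (m_per_deg_lat
                                            * np.cos(np.radians(lat_ref)))

        collars = [f"{herd_id}A{a + 1:02d}" for a in range(n_animals)]
        keep = slice(n_burn, n_slots)
        n_out = n_slots - n_burn
        frame = pd.DataFrame({
            "collar_id": np.repeat(collars, n_out),
            "herd_id": herd_id,
            "species": sp,
            "slot_time": np.tile(slot_times[keep], n_animals),
            "true_state": np.array(STATE_NAMES)[states[keep].T.ravel()],
            "lat": lats[keep].T.ravel(),
            "lon": lons[keep].T.ravel(),
        })
        frames.append(frame)

    truth = pd.concat(frames, ignore_index=True)
    transmitted = _transmission_mask(truth, cfg,
                                     np.random.default_rng(root.spawn(1)[0]))
    truth["transmitted"] = transmitted

    fixes = truth.loc[truth["transmitted"],
                      ["collar_id", "herd_id", "species", "slot_time",
                       "lat", "lon"]].rename(columns={"slot_time": "timestamp"})
    fixes["altitude_m"] = np.nan
    if terrain is not None:
        sampled = sample_terrain(terrain, fixes["lat"].to_numpy(),
                                 fixes["lon"].to_numpy())
        fixes["altitude_m"] = sampled["altitude_m"].to_numpy()
    fixes["quality"] = "observed"
    fixes = (fixes[FIX_COLUMNS].sort_values(["collar_id", "timestamp"])
             .reset_index(drop=True))
    return truth, fixes


def _transmission_mask(truth: pd.DataFrame, cfg: SimConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Per-fix Bernoulli delivery plus per-collar-day burst outages."""
    n = len(truth)
    keep = rng.random(n) >= cfg.msg_loss_rate
    if cfg.burst_gap_rate > 0:
        dates = truth["slot_time"].dt.date
        slot_in_day = (truth["slot_time"].dt.hour * 2
                       + truth["slot_time"].dt.minute // 30).to_numpy()
        for (_, _), idx in truth.groupby([truth["collar_id"], dates],
                                         sort=True).indices.items():
            if rng.random() < cfg.burst_gap_rate:
                hours = rng.uniform(*cfg.burst_hours)
                length = int(round(hours * 2))
                start = rng.integers(0, SLOTS_PER_DAY)
                sl = slot_in_day[idx]
                keep[idx[(sl >= start) & (sl < start + length)]] = False
    return keep


def degrade(fixes: pd.DataFrame, msg_loss_rate: float,
            burst_gap_rate: float = 0.0, seed: int = 0,
            burst_hours: tuple = (6.0, 14.0)) -> pd.DataFrame:
    """Thin an on-grid fix table by message loss and burst outages.

    The expected retained fraction is ``(1 - msg_loss_rate)`` times the
    expected fraction outside burst windows; the retained subset is
    reproducible per seed.
    """
    if msg_loss_rate == 0 and burst_gap_rate == 0:
        return fixes.copy()
    cfg = SimConfig(msg_loss_rate=msg_loss_rate,
                    burst_gap_rate=burst_gap_rate, burst_hours=burst_hours)
    table = fixes.rename(columns={"timestamp": "slot_time"})
    keep = _transmission_mask(table, cfg, np.random.default_rng(seed))
    return fixes.loc[keep].reset_index(drop=True)


def simulate(cfg: SimConfig | None = None, with_terrain: bool = True
             ) -> tuple[pd.DataFrame, pd.DataFrame, TerrainGrid | None]:
    """Convenience wrapper: terrain + herds in one call, all from cfg.seed."""
    cfg = cfg or SimConfig()
    terrain = simulate_terrain(seed=cfg.seed) if with_terrain else None
    truth, fixes = simulate_herds(cfg, terrain)
    return truth, fixes, terrain
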