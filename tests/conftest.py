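import numpy as np
import pandas as pd
import pytest

import herdtrack as ht
from herdtrack.cleaning import DayBatch


def make_batch(times, lats, lons, collar_id="C1", herd_id="H1",
               species="bovine", date=None):
    """Build a DayBatch from UTC time strings and coordinate lists."""
    ts = pd.to_datetime(list(times), utc=True)
    fixes = pd.DataFrame({
        "collar_id": collar_id, "herd_id": herd_id, "species": species,
        "timestamp": ts, "lat": np.asarray(lats, float),
        "lon": np.asarray(lons, float),
        "altitude_m": np.nan, "quality": "observed",
    })
    return DayBatch(collar_id=collar_id, date=date or ts[0].date(), fixes=fixes)


def grid_day_batch(lat0=42.4, lon0=1.2, dlat=0.0001, n=48, date="2022-06-01",
                   **kw):
    """A full day of fixes already exactly on the 30-min grid, moving north."""
    times = pd.date_range(f"{date} 00:00", periods=n, freq="30min", tz="UTC")
    lats = lat0 + dlat * np.arange(n)
    lons = np.full(n, lon0)
    return make_batch(times, lats, lons, **kw)


@pytest.fixture(scope="session")
def small_sim():
    """A small but non-trivial simulation shared by read-mostly tests."""
    cfg = ht.SimConfig(days=4, animals_per_herd=4,
                       species_by_herd=("bovine", "ovine"), seed=11)
    truth, fixes, terrain = ht.simulate(cfg)
    return cfg, truth, fixes, terrain


@pytest.fixture(scope="session")
def full_run():
    """Full study-condition simulation plus the complete pipeline output."""
    cfg = ht.SimConfig(seed=202)
    truth, fixes, terrain = ht.simulate(cfg)
    result = ht.run_pipeline(fixes, terrain=terrain)
    return cfg, truth, fixes, result
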