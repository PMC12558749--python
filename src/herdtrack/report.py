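"""Seasonal / species summary tables and the modeling-ready export.

Descriptive aggregation only: per-group mean, SD, n, max, min of the daily
indicators, with a configurable season rule (default: astronomical
boundaries — spring before the June solstice, summer to the September
equinox, autumn after). Mixed-model fitting is deliberately left to
downstream statistical tools; :func:`modeling_table` emits the tidy table
(with log-transformed daily distance and home range) such a model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date

import numpy as np
import pandas as pd

#: Grazing-season months covered by the default rule.
SEASONS = ("spring", "summer", "autumn")


@dataclass
class SeasonRule:
    """Maps dates to grazing-season thirds by (month, day) boundaries.

    Defaults are the astronomical boundaries: the June solstice (Jun 21)
    opens summer and the September equinox (Sep 22) opens autumn; everything
    earlier in the year is spring.
    """

    summer_start: tuple = (6, 21)
    autumn_start: tuple = (9, 22)

    def season_of(self, d) -> str:
        d = pd.Timestamp(d)
        md = (d.month, d.day)
        if md < self.summer_start:
            return "spring"
        if md < self.autumn_start:
            return "summer"
        return "autumn"


def season_of(d, rule: SeasonRule | None = None) -> str:
    """Season of a calendar date under a rule (default astronomical)."""
    return (rule or SeasonRule()).season_of(d)


def summarize(table: pd.DataFrame, group_by, value_col: str) -> pd.DataFrame:
    """Per-group mean, sd, n, max, min of one metric column.

    Missing values are excluded (count logged in the ``n_missing`` column);
    single-observation groups get NaN sd (flagged, not an error).
    """
    if table.empty:
        raise ValueError("cannot summarize an empty table")
    if isinstance(group_by, str):
        group_by = [group_by]
    if not group_by:
        raise ValueError("group_by must name at least one column")
    g = table.groupby(group_by, observed=True)[value_col]
    out = g.agg(mean="mean", sd="std", n="count", max="max", min="min")
    out["n_missing"] = g.apply(lambda s: int(s.isna().sum()))
    return out.reset_index()


def seasonal_summary(daily_metrics: pd.DataFrame,
                     hr: pd.DataFrame | None = None,
                     dispersal: pd.DataFrame | None = None,
                     rule: SeasonRule | None = None) -> pd.DataFrame:
    """Species-by-season summary of daily distance, HR and dispersal.

    One row per (species, season, metric) in the long layout of a results
    table: metric in {daily_distance_km, hr_ha, dispersal_m}.
    """
    rule = rule or SeasonRule()
    parts = []

    dm = daily_metrics.copy()
    dm["season"] = dm["date"].map(rule.season_of)
    s = summarize(dm, ["species", "season"], "path_km")
    s["metric"] = "daily_distance_km"
    parts.append(s)

    if hr is not None and not hr.empty:
        h = hr.copy()
        h["season"] = h["date"].map(rule.season_of)
        s = summarize(h, ["species", "season"], "area_ha")
        s["metric"] = "hr_ha"
        parts.append(s)

    if dispersal is not None and not dispersal.empty:
        dd = dispersal.copy()
        dd["season"] = dd["slot_time"].dt.date.map(rule.season_of)
        s = summarize(dd, ["species", "season"], "dist_to_centroid_m")
        s["metric"] = "dispersal_m"
        parts.append(s)

    cols = ["species", "season", "metric", "mean", "sd", "n", "max", "min"]
    return pd.concat(parts, ignore_index=True)[cols]


def modeling_table(daily_metrics: pd.DataFrame,
                   hr: pd.DataFrame | None = None,
                   weather: pd.DataFrame | None = None,
                   rule: SeasonRule | None = None) -> pd.DataFrame:
    """Tidy per-collar-day table ready for mixed-model fitting elsewhere.

    Includes log-transformed daily distance and home range (the transforms a
    normal-errors model of these right-skewed metrics needs) plus season and
    year factors; weather columns are joined by date when given.
    """
    rule = rule or SeasonRule()
    out = daily_metrics.copy()
    out["season"] = out["date"].map(rule.season_of)
    out["year"] = pd.to_datetime(out["date"]).dt.year
    with np.errstate(divide="ignore"):
        out["log_path_km"] = np.log(out["path_km"].where(out["path_km"] > 0))
    if hr is not None and not hr.empty:
        out = out.merge(hr[["collar_id", "date", "area_ha"]],
                        on=["collar_id", "date"], how="left")
        with np.errstate(divide="ignore"):
            out["log_area_ha"] = np.log(out["area_ha"].where(out["area_ha"] > 0))
    if weather is not None and not weather.empty:
        wx = weather.drop(columns=["station_id"], errors="ignore")
        wx = wx.groupby("date", as_index=False).mean(numeric_only=True)
        out = out.merge(wx, on="date", how="left")
    return out
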