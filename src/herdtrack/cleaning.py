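"""Day-level quality control and implausible-trajectory rejection.

Raw collar data are filtered per collar-day before any resampling:

1. days with fewer than 10 transmissions, or a gap of more than 12 consecutive
   hours between transmissions, are dropped;
2. days whose raw track covers more than 10 km, or contains a single step of
   more than 4 km, are rejected as not being natural distances.

All thresholds are strict ("less than 10", "more than 12/10/4"): boundary
values pass. Gaps from midnight to the first fix, or from the last fix to
midnight, do not count toward the gap rule — only intervals *between*
transmissions do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import haversine_m


@dataclass
class QCConfig:
    min_messages_per_day: int = 10
    max_gap_hours: float = 12.0
    max_daily_km: float = 10.0
    max_step_km: float = 4.0

    def __post_init__(self) -> None:
        for name in ("min_messages_per_day", "max_gap_hours",
                     "max_daily_km", "max_step_km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class DayBatch:
    """All fixes of one collar within one UTC calendar day, in time order."""

    collar_id: str
    date: object  # datetime.date
    fixes: pd.DataFrame

    def __len__(self) -> int:
        return len(self.fixes)


def partition_days(fixes: pd.DataFrame) -> list[DayBatch]:
    """Split a sorted fix table into per-collar, midnight-to-midnight batches.

    Days are half-open ``[00:00, 24:00)``: a fix at exactly midnight belongs to
    the day it begins. Empty batches are never emitted.
    """
    if fixes.empty:
        return []
    dates = fixes["timestamp"].dt.date
    batches = []
    for (collar, date), grp in fixes.groupby([fixes["collar_id"], dates], sort=True):
        batches.append(DayBatch(collar_id=str(collar), date=date,
                                fixes=grp.reset_index(drop=True)))
    return batches


def qc_day(batch: DayBatch, cfg: QCConfig | None = None) -> tuple[bool, str]:
    """Apply the message-count and gap filters to one collar-day.

    Returns ``(keep, reason)`` with reason one of ``ok``, ``too_few_messages``,
    ``long_gap`` (the first failing rule, in that order).
    """
    cfg = cfg or QCConfig()
    n = len(batch.fixes)
    if n == 0:
        raise ValueError("qc_day requires a non-empty batch")
    if n < cfg.min_messages_per_day:
        return False, "too_few_messages"
    if n >= 2:
        gaps = batch.fixes["timestamp"].diff().dropna().dt.total_seconds() / 3600.0
        if (gaps > cfg.max_gap_hours).any():
            return False, "long_gap"
    return True, "ok"


def raw_trajectory_metrics(batch: DayBatch) -> dict[str, float]:
    """Path length and maximum step of the raw (pre-resampling) day track, km."""
    lat = batch.fixes["lat"].to_numpy()
    lon = batch.fixes["lon"].to_numpy()
    if len(lat) < 2:
        return {"path_km": 0.0, "max_step_km": 0.0}
    steps = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:]) / 1000.0
    return {"path_km": float(steps.sum()), "max_step_km": float(steps.max())}


def reject_implausible(traj_metrics: dict[str, float],
                       cfg: QCConfig | None = None) -> tuple[bool, str]:
    """Reject a day whose raw track is too long overall or in a single step.

    Strict inequalities: exactly 10 km of path or a 4 km step is kept.
    """
    cfg = cfg or QCConfig()
    if traj_metrics["path_km"] > cfg.max_daily_km:
        return False, "excess_daily_distance"
    if traj_metrics["max_step_km"] > cfg.max_step_km:
        return False, "excess_step"
    return True, "ok"


def clean(fixes: pd.DataFrame, cfg: QCConfig | None = None
          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run both QC stages over a fix table.

    Returns ``(kept_fixes, audit)``. The audit has one row per collar-day with
    columns ``collar_id, date, n_fixes, keep, reason, path_km, max_step_km``;
    its attrs carry the retention bookkeeping both ways the deletion fraction
    can be counted (``retention_fixes`` and ``retention_days``).
    """
    cfg = cfg or QCConfig()
    rows = []
    kept_parts = []
    for batch in partition_days(fixes):
        keep, reason = qc_day(batch, cfg)
        metrics = {"path_km": np.nan, "max_step_km": np.nan}
        if keep:
            metrics = raw_trajectory_metrics(batch)
            keep, reason = reject_implausible(metrics, cfg)
        rows.append({"collar_id": batch.collar_id, "date": batch.date,
                     "n_fixes": len(batch), "keep": keep, "reason": reason,
                     "path_km": metrics["path_km"],
                     "max_step_km": metrics["max_step_km"]})
        if keep:
            kept_parts.append(batch.fixes)
    audit = pd.DataFrame(rows, columns=["collar_id", "date", "n_fixes", "keep",
                                        "reason", "path_km", "max_step_km"])
    kept = (pd.concat(kept_parts, ignore_index=True) if kept_parts
            else fixes.iloc[0:0].copy())
    total_fixes = int(audit["n_fixes"].sum()) if len(audit) else 0
    kept_fixes_n = int(audit.loc[audit["keep"], "n_fixes"].sum()) if len(audit) else 0
    audit.attrs["retention_fixes"] = (kept_fixes_n / total_fixes) if total_fixes else np.nan
    audit.attrs["retention_days"] = (float(audit["keep"].mean()) if len(audit)
                                     else np.nan)
    return kept, audit
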