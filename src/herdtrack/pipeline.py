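"""End-to-end convenience pipeline: raw fixes in, all indicators out.

Mirrors the processing order of the collar study: day-level QC -> raw-track
implausibility filter -> resampling to the 48-slot grid -> Savitzky-Golay
smoothing -> indicators (movement, behavior, home range, dispersal, diel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import behavior, cleaning, diel, space_use, trajectory


@dataclass
class PipelineResult:
    kept_fixes: pd.DataFrame
    audit: pd.DataFrame
    trajectories: list
    daily_metrics: pd.DataFrame
    labels: pd.DataFrame
    thresholds: behavior.ThresholdSet
    home_ranges: pd.DataFrame
    dispersal: pd.DataFrame
    diel_partition: pd.DataFrame


def run_pipeline(fixes: pd.DataFrame,
                 terrain=None,
                 qc: cleaning.QCConfig | None = None,
                 smoothing: trajectory.SmoothingConfig | None = None,
                 smooth: bool = True,
                 mcp_percent: float = 95.0,
                 solar: diel.SolarConfig | None = None) -> PipelineResult:
    """Run every stage on a raw fix table and return all result tables."""
    kept, audit = cleaning.clean(fixes, qc)
    trajs = trajectory.build_daily_trajectories(kept, smoothing, smooth=smooth)
    metrics = trajectory.daily_metrics_table(trajs)
    steps = behavior.label_steps(trajs, terrain=terrain)
    thresholds = behavior.fit_thresholds(steps)
    labels = behavior.classify_table(steps, thresholds)
    hr = space_use.daily_home_ranges(trajs, percent=mcp_percent)
    disp = space_use.dispersal(trajs)
    diel_part = diel.diel_table(trajs, solar)
    return PipelineResult(kept_fixes=kept, audit=audit, trajectories=trajs,
                          daily_metrics=metrics, labels=labels,
                          thresholds=thresholds, home_ranges=hr,
                          dispersal=disp, diel_partition=diel_part)
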