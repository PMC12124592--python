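"""End-to-end orchestration: simulate/load -> measure -> exclude -> infer.

``run_pipeline`` produces, per run: the per-trial measures table, the
exclusion report, a statistics report (choice tests, 2x2 rmANOVAs per
measure, interaction-gated follow-up t-tests) and per-condition mean
time-normalized trajectories (point-wise average over each participant's
valid paths first, then across participants).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import exclusion as excl
from . import inference as inf
from .geometry import GEOMETRY_VARIANTS, ScreenGeometry
from .io import read_session, session_from_frames, write_measures
from .preprocess import N_NORM_POINTS, measure_session
from .simulate import SimConfig, generate_session

__all__ = ["PipelineConfig", "run_pipeline", "mean_trajectories"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration.

    Exactly one input source must be set: either ``simulation`` or the
    ``trials_path``/``samples_path`` pair.  Cutoff overrides are surfaced in
    the report header so no flag can silently change a preregistered value.
    """

    simulation: SimConfig | None = None
    trials_path: str | None = None
    samples_path: str | None = None
    geometry: str = "image"  # image (100x100 targets) | text (250x50)
    out_dir: str | None = None
    cutoff_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        has_files = self.trials_path is not None
        if has_files == (self.simulation is not None):
            raise ValueError("exactly one input source: files XOR simulation")
        if self.geometry not in GEOMETRY_VARIANTS:
            raise ValueError(f"unknown geometry variant {self.geometry!r}")
        for key, value in self.cutoff_overrides.items():
            if key not in excl.CUTOFFS:
                raise ValueError(f"unknown cutoff {key!r}")
            if key != "auc_min_xu2" and value <= 0:
                raise ValueError(f"cutoff {key!r} must be positive")


def mean_trajectories(
    measures: pd.DataFrame, paths: dict[tuple, "object"]
) -> pd.DataFrame:
    """Per-condition grand-average of the 101-point normalized paths.

    Valid trials of included participants are averaged point-wise within
    each participant and condition first, then across participants, so every
    participant contributes equally.  The appended 102nd (dwell) point is
    not part of the average.
    """
    ok = measures[~measures["excluded"] & measures["participant_included"]]
    rows = []
    for (ctype, innov), grp in ok.groupby(
        ["comparison_type", "chosen_innovativeness"], sort=False
    ):
        per_participant = []
        for pid, sub in grp.groupby("participant_id", sort=False):
            stack = [
                paths[key].points[:N_NORM_POINTS]
                for key in zip(sub["participant_id"], sub["block"], sub["trial_index"])
                if key in paths
            ]
            if stack:
                per_participant.append(np.mean(stack, axis=0))
        if not per_participant:
            continue
        grand = np.mean(per_participant, axis=0)
        for i, (x, y) in enumerate(grand):
            rows.append(
                {
                    "comparison_type": ctype,
                    "innovativeness": innov,
                    "point": i,
                    "x_xu": x,
                    "y_xu": y,
                    "n_participants": len(per_participant),
                }
            )
    return pd.DataFrame(rows)


def _stats_report(measures: pd.DataFrame, cells: pd.DataFrame, config: PipelineConfig):
    report: dict = {
        "geometry": config.geometry,
        "cutoffs": {**excl.CUTOFFS, **config.cutoff_overrides},
        "cutoff_overrides": dict(config.cutoff_overrides),
        "n_participants_total": int(measures["participant_id"].nunique()),
        "n_participants_included": int(
            measures.loc[measures["participant_included"], "participant_id"].nunique()
        ),
        "choice_tests": {},
        "measures": {},
    }
    for ctype in ("past", "future"):
        try:
            res = inf.choice_frequency_test(measures, ctype)
            report["choice_tests"][ctype] = res.to_dict()
        except inf.DegenerateDataError as err:
            log.warning("[inference] choice test (%s) degenerate: %s", ctype, err)
            report["choice_tests"][ctype] = {"degenerate": str(err)}
    for measure in ("it", "mt", "auc"):
        anova = inf.rm_anova_2x2(cells, measure)
        entry: dict = {"anova": [a.to_dict() for a in anova], "follow_up": {}}
        interaction = next(a for a in anova if a.effect == "interaction")
        gated = bool(interaction.p < 0.05)
        entry["follow_up_evaluated"] = gated
        if gated:
            for ctype in ("past", "future"):
                entry["follow_up"][ctype] = inf.paired_t(cells, ctype, measure).to_dict()
        report["measures"][measure] = entry
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns all artifacts and optionally writes them.

    Returns a dict with keys ``measures`` (DataFrame), ``exclusion_report``
    (:class:`~mousetrace.exclusion.ExclusionReport`), ``stats_report``
    (dict), ``cells`` (DataFrame) and ``mean_trajectories`` (DataFrame).
    """
    geom: ScreenGeometry = GEOMETRY_VARIANTS[config.geometry]()
    if config.simulation is not None:
        log.info("[simulate] generating session (seed=%d)", config.simulation.seed)
        trials_df, samples_df, _truth = generate_session(config.simulation, geom)
        trials = session_from_frames(trials_df, samples_df)
    else:
        log.info("[load] reading session from %s", config.trials_path)
        trials = read_session(config.trials_path, config.samples_path)
    log.info("[measure] %d trials", len(trials))
    measures, paths = measure_session(trials, geom)
    measures, report = excl.run_exclusions(measures, config.cutoff_overrides or None)
    cells = inf.summarize_cells(measures)
    log.info(
        "[infer] %d participants in performance analyses",
        cells["participant_id"].nunique(),
    )
    stats = _stats_report(measures, cells, config)
    mean_traj = mean_trajectories(measures, paths)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_measures(measures, out / "measures.csv")
        report.save(out / "exclusion_report.json")
        (out / "stats_report.json").write_text(json.dumps(stats, indent=2))
        mean_traj.to_csv(out / "mean_trajectories.csv", index=False)
        log.info("[report] artifacts written to %s", out)

    return {
        "measures": measures,
        "exclusion_report": report,
        "stats_report": stats,
        "cells": cells,
        "mean_trajectories": mean_traj,
    }
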