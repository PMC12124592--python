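"""Preregistered trial- and participant-level exclusion cascade.

Stage order is fixed:

1. error trials (clicked option contradicts the declared intention);
2. trials whose movement could not be measured (no target entry);
3. absolute cutoffs: IT > 3000 ms, MT > 5000 ms, AUC > 30000 xu^2 or
   AUC < -20000 xu^2 (strict inequalities);
4. trials with fewer than 3 samples in the movement window;
5. a single-pass 2.5-SD filter around each participant x design-cell mean,
   applied per measure to the trials surviving stages 1-4;
6. participants with fewer than 10 valid trials in any of the four design
   cells are dropped from performance analyses (never from choice counts).

Each trial carries exactly one exclusion reason — the first stage that fires.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CUTOFFS",
    "ExclusionReport",
    "EmptyCohortError",
    "apply_error_filter",
    "apply_absolute_cutoffs",
    "apply_min_samples_filter",
    "apply_cell_sd_filter",
    "include_participants",
    "run_exclusions",
]

log = logging.getLogger(__name__)

#: preregistered absolute cutoffs (strict inequalities)
CUTOFFS = {
    "it_max_ms": 3000.0,
    "mt_max_ms": 5000.0,
    "auc_max_xu2": 30000.0,
    "auc_min_xu2": -20000.0,
}

MIN_SAMPLES = 3
SD_CRITERION = 2.5
MIN_VALID_PER_CELL = 10

CELL_KEYS = ["participant_id", "comparison_type", "chosen_innovativeness"]


class EmptyCohortError(RuntimeError):
    """No participant survives the inclusion criterion."""


@dataclass
class ExclusionReport:
    """Counts and bookkeeping for every stage of the cascade."""

    n_trials: int = 0
    stage_counts: dict[str, int] = field(default_factory=dict)
    participants_excluded: list[str] = field(default_factory=list)
    valid_trials_per_cell: pd.DataFrame | None = None
    small_cells_skipped_by_sd_filter: list[tuple] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return sum(self.stage_counts.values())

    def to_dict(self) -> dict:
        cells = (
            self.valid_trials_per_cell.to_dict(orient="records")
            if self.valid_trials_per_cell is not None
            else []
        )
        return {
            "n_trials": self.n_trials,
            "n_excluded": self.n_excluded,
            "stage_counts": self.stage_counts,
            "participants_excluded": list(self.participants_excluded),
            "valid_trials_per_cell": cells,
            "small_cells_skipped_by_sd_filter": [
                list(c) for c in self.small_cells_skipped_by_sd_filter
            ],
        }

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def _open(df: pd.DataFrame) -> pd.Series:
    """Trials not yet claimed by an earlier stage."""
    return df["exclusion_reason"] == "none"


def apply_error_filter(measures: pd.DataFrame) -> pd.DataFrame:
    """Exclude error trials from performance analyses (stage 1)."""
    df = measures.copy()
    hit = _open(df) & df["error"]
    df.loc[hit, "exclusion_reason"] = "error"
    return df


def apply_absolute_cutoffs(
    measures: pd.DataFrame, cutoffs: dict[str, float] | None = None
) -> pd.DataFrame:
    """Apply the preregistered absolute cutoffs (stage 3, strict bounds)."""
    c = {**CUTOFFS, **(cutoffs or {})}
    df = measures.copy()
    hit = _open(df) & (df["it_ms"] > c["it_max_ms"])
    df.loc[hit, "exclusion_reason"] = "it_cutoff"
    hit = _open(df) & (df["mt_ms"] > c["mt_max_ms"])
    df.loc[hit, "exclusion_reason"] = "mt_cutoff"
    hit = _open(df) & (
        (df["auc_xu2"] > c["auc_max_xu2"]) | (df["auc_xu2"] < c["auc_min_xu2"])
    )
    df.loc[hit, "exclusion_reason"] = "auc_cutoff"
    return df


def apply_min_samples_filter(measures: pd.DataFrame) -> pd.DataFrame:
    """Exclude trials with fewer than 3 movement-window samples (stage 4)."""
    df = measures.copy()
    hit = _open(df) & (df["n_samples"] < MIN_SAMPLES)
    df.loc[hit, "exclusion_reason"] = "too_few_points"
    return df


def apply_cell_sd_filter(
    measures: pd.DataFrame, report: ExclusionReport | None = None
) -> pd.DataFrame:
    """Single-pass 2.5-SD outlier filter within each design cell (stage 5).

    For each participant x comparison-type x innovativeness cell and each of
    IT/MT/AUC, trials deviating more than 2.5 sample SDs from the cell mean
    (both computed on the trials surviving earlier stages) are excluded.  The
    filter is deliberately single-pass: means and SDs are not recomputed
    after removals.  Cells with fewer than 2 surviving trials have no defined
    SD and are skipped (logged on the report).
    """
    df = measures.copy()
    surviving = _open(df)
    outlier = pd.Series(False, index=df.index)
    for key, idx in df[surviving].groupby(CELL_KEYS, sort=False).groups.items():
        sub = df.loc[idx]
        if len(sub) < 2:
            log.info("SD filter skipped cell %s (n=%d < 2)", key, len(sub))
            if report is not None:
                report.small_cells_skipped_by_sd_filter.append(key)
            continue
        for col in ("it_ms", "mt_ms", "auc_xu2"):
            vals = sub[col].to_numpy(dtype=float)
            mean = np.nanmean(vals)
            sd = np.nanstd(vals, ddof=1)
            dev = np.abs(vals - mean)
            outlier.loc[idx] |= dev > SD_CRITERION * sd
    hit = surviving & outlier
    df.loc[hit, "exclusion_reason"] = "sd_outlier"
    return df


def include_participants(
    measures: pd.DataFrame,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Participant-level inclusion (stage 6) and final report.

    Participants need at least 10 valid trials in each of the four design
    cells to enter performance analyses; choice-frequency analyses keep the
    full cohort.  Adds a ``participant_included`` column and finalizes
    ``excluded``.
    """
    df = measures.copy()
    df["excluded"] = df["exclusion_reason"] != "none"
    valid = df[~df["excluded"]]
    counts = (
        valid.groupby(CELL_KEYS, sort=False, observed=True)
        .size()
        .rename("n_valid")
        .reset_index()
    )

    participants = df["participant_id"].unique()
    cells = [("past", "high"), ("past", "low"), ("future", "high"), ("future", "low")]
    excluded_participants = []
    for pid in participants:
        sub = counts[counts["participant_id"] == pid]
        by_cell = {
            (r.comparison_type, r.chosen_innovativeness): r.n_valid
            for r in sub.itertuples()
        }
        if any(by_cell.get(c, 0) < MIN_VALID_PER_CELL for c in cells):
            excluded_participants.append(pid)
    df["participant_included"] = ~df["participant_id"].isin(excluded_participants)

    if len(excluded_participants) == len(participants) and len(participants) > 0:
        raise EmptyCohortError(
            "no participant has >= "
            f"{MIN_VALID_PER_CELL} valid trials in every design cell"
        )

    report = ExclusionReport(
        n_trials=len(df),
        stage_counts={
            reason: int((df["exclusion_reason"] == reason).sum())
            for reason in (
                "error",
                "no_target_entry",
                "it_cutoff",
                "mt_cutoff",
                "auc_cutoff",
                "too_few_points",
                "sd_outlier",
            )
        },
        participants_excluded=sorted(excluded_participants),
        valid_trials_per_cell=counts,
    )
    return df, report


def run_exclusions(
    measures: pd.DataFrame, cutoffs: dict[str, float] | None = None
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Run the full cascade in its fixed order and return the report.

    Input rows must carry measurement-level reasons (``no_target_entry``,
    ``too_few_points``) already set where kinematics were unmeasurable; the
    cascade re-derives all other reasons from scratch, giving error trials
    first claim.
    """
    df = measures.copy()
    # stage 1 outranks measurement-level flags, so lift those first
    premeasure = df["exclusion_reason"].where(
        df["exclusion_reason"].isin(["no_target_entry", "too_few_points"]), "none"
    )
    df["exclusion_reason"] = "none"
    df = apply_error_filter(df)
    restore = _open(df) & (premeasure == "no_target_entry")
    df.loc[restore, "exclusion_reason"] = "no_target_entry"
    df = apply_absolute_cutoffs(df, cutoffs)
    restore = _open(df) & (premeasure == "too_few_points")
    df.loc[restore, "exclusion_reason"] = "too_few_points"
    df = apply_min_samples_filter(df)
    report_stub = ExclusionReport()
    df = apply_cell_sd_filter(df, report_stub)
    df, report = include_participants(df)
    report.small_cells_skipped_by_sd_filter = (
        report_stub.small_cells_skipped_by_sd_filter
    )
    for reason, count in report.stage_counts.items():
        log.info("[exclusion] %s: %d trials", reason, count)
    log.info(
        "[exclusion] participants excluded: %d of %d",
        len(report.participants_excluded),
        df["participant_id"].nunique(),
    )
    return df, report
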