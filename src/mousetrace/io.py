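"""Reading and writing session logs and derived measure tables.

A session is stored as two CSV files: ``trials.csv`` with one row of metadata
per trial and ``samples.csv`` with the cursor stream in long format, joined on
``(participant_id, block, trial_index)``.  Timestamps are milliseconds on a
single session clock shared with ``onset_ms``.  Raw coordinates are
screen-native pixels (y grows downward) at the participant's display scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RawTrial",
    "SchemaError",
    "SessionValidationError",
    "read_session",
    "session_from_frames",
    "write_session",
    "write_measures",
    "read_measures",
    "INNOVATIVENESS_RANK",
    "COMPARISON_PAIRS",
]

TRIALS_COLUMNS = [
    "participant_id",
    "experiment_id",
    "block",
    "trial_index",
    "category",
    "comparison_type",
    "intention",
    "option_left",
    "option_right",
    "clicked_side",
    "onset_ms",
    "display_scale",
]

SAMPLES_COLUMNS = ["participant_id", "block", "trial_index", "t_ms", "x_px", "y_px"]

MEASURES_COLUMNS = [
    "participant_id",
    "experiment_id",
    "block",
    "trial_index",
    "category",
    "comparison_type",
    "intention",
    "chosen_option",
    "chosen_innovativeness",
    "it_ms",
    "mt_ms",
    "auc_xu2",
    "n_samples",
    "error",
    "excluded",
    "exclusion_reason",
]

#: rank of each option on the tradition -> innovation axis
INNOVATIVENESS_RANK = {"historic": 0, "contemporary": 1, "innovative": 2}

#: option pair presented for each comparison type
COMPARISON_PAIRS = {
    "past": frozenset({"historic", "contemporary"}),
    "future": frozenset({"contemporary", "innovative"}),
}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class SessionValidationError(ValueError):
    """A trial violates a structural invariant (e.g. non-monotone timestamps)."""


@dataclass
class RawTrial:
    """One trial's metadata plus its raw cursor stream.

    ``samples`` is an ``(n, 3)`` float array of ``(t_ms, x_px, y_px)`` rows,
    strictly increasing in ``t_ms``, in the participant's native pixel frame.
    """

    participant_id: str
    experiment_id: str
    block: int
    trial_index: int
    category: str
    comparison_type: str
    intention: str
    option_left: str
    option_right: str
    clicked_side: str
    onset_ms: float
    display_scale: float
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1, 3)
        if self.comparison_type not in COMPARISON_PAIRS:
            raise SessionValidationError(
                f"{self.key}: unknown comparison_type {self.comparison_type!r}"
            )
        pair = {self.option_left, self.option_right}
        if pair != set(COMPARISON_PAIRS[self.comparison_type]):
            raise SessionValidationError(
                f"{self.key}: options {sorted(pair)} do not match "
                f"{self.comparison_type!r} comparison"
            )
        if self.clicked_side not in ("left", "right"):
            raise SessionValidationError(f"{self.key}: bad clicked_side")
        t = self.samples[:, 0]
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise SessionValidationError(
                f"{self.key}: sample timestamps are not strictly increasing"
            )

    @property
    def key(self) -> tuple:
        return (self.participant_id, self.block, self.trial_index)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def chosen_option(self) -> str:
        return self.option_left if self.clicked_side == "left" else self.option_right

    @property
    def unchosen_option(self) -> str:
        return self.option_right if self.clicked_side == "left" else self.option_left

    @property
    def chosen_innovativeness(self) -> str:
        """'high' if the clicked option is the more innovative of the pair."""
        chosen = INNOVATIVENESS_RANK[self.chosen_option]
        other = INNOVATIVENESS_RANK[self.unchosen_option]
        return "high" if chosen > other else "low"

    @property
    def is_error(self) -> bool:
        """Clicked option contradicts the declared intention for the trial."""
        intended_high = self.intention == "more_innovative"
        return (self.chosen_innovativeness == "high") != intended_high


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} is missing required column {col!r}")


def _resolve_paths(path, samples_path) -> tuple[Path, Path]:
    path = Path(path)
    if samples_path is not None:
        return path, Path(samples_path)
    if path.is_dir():
        return path / "trials.csv", path / "samples.csv"
    return path, path.parent / "samples.csv"


def read_session(path, samples_path=None) -> list[RawTrial]:
    """Read a session from ``trials.csv`` + ``samples.csv``.

    ``path`` may be a directory containing both files, or the trials CSV
    (with the samples CSV given explicitly or found as a sibling).  Returns
    one :class:`RawTrial` per trials row, with samples joined by
    ``(participant_id, block, trial_index)`` and sorted by ``t_ms``.  Trials
    without any samples are kept (with an empty stream) and a warning is
    issued; downstream measurement flags them as unusable.
    """
    trials_path, samples_path = _resolve_paths(path, samples_path)
    trials = pd.read_csv(trials_path, dtype={"participant_id": str})
    samples = pd.read_csv(samples_path, dtype={"participant_id": str})
    _require_columns(trials, TRIALS_COLUMNS, str(trials_path))
    _require_columns(samples, SAMPLES_COLUMNS, str(samples_path))
    return session_from_frames(trials, samples)


def session_from_frames(trials: pd.DataFrame, samples: pd.DataFrame) -> list[RawTrial]:
    """Join a trials table and a long samples table into RawTrial objects."""
    _require_columns(trials, TRIALS_COLUMNS, "trials table")
    _require_columns(samples, SAMPLES_COLUMNS, "samples table")
    trials = trials.sort_values(
        ["participant_id", "block", "trial_index"], kind="stable"
    )
    samples = samples.sort_values(
        ["participant_id", "block", "trial_index", "t_ms"], kind="stable"
    )
    grouped = {
        key: grp[["t_ms", "x_px", "y_px"]].to_numpy(dtype=float)
        for key, grp in samples.groupby(
            ["participant_id", "block", "trial_index"], sort=False
        )
    }

    out: list[RawTrial] = []
    for row in trials.itertuples(index=False):
        key = (row.participant_id, int(row.block), int(row.trial_index))
        stream = grouped.get(key, np.empty((0, 3)))
        if len(stream) == 0:
            warnings.warn(f"trial {key} has no cursor samples", stacklevel=2)
        out.append(
            RawTrial(
                participant_id=str(row.participant_id),
                experiment_id=str(row.experiment_id),
                block=int(row.block),
                trial_index=int(row.trial_index),
                category=str(row.category),
                comparison_type=str(row.comparison_type),
                intention=str(row.intention),
                option_left=str(row.option_left),
                option_right=str(row.option_right),
                clicked_side=str(row.clicked_side),
                onset_ms=float(row.onset_ms),
                display_scale=float(row.display_scale),
                samples=stream,
            )
        )
    return out


def write_session(trials: pd.DataFrame, samples: pd.DataFrame, out_dir) -> tuple[Path, Path]:
    """Write a session's two tables under ``out_dir`` in the canonical schema."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _require_columns(trials, TRIALS_COLUMNS, "trials table")
    _require_columns(samples, SAMPLES_COLUMNS, "samples table")
    trials_path = out_dir / "trials.csv"
    samples_path = out_dir / "samples.csv"
    trials[TRIALS_COLUMNS].to_csv(trials_path, index=False)
    samples[SAMPLES_COLUMNS].to_csv(samples_path, index=False)
    return trials_path, samples_path


def write_measures(measures: pd.DataFrame, path) -> Path:
    """Write a per-trial measures table; round-trip safe via :func:`read_measures`."""
    path = Path(path)
    _require_columns(measures, MEASURES_COLUMNS, "measures table")
    measures[MEASURES_COLUMNS].to_csv(path, index=False)
    return path


def read_measures(path) -> pd.DataFrame:
    """Read back a measures table written by :func:`write_measures`."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, MEASURES_COLUMNS, str(path))
    df["error"] = df["error"].astype(bool)
    df["excluded"] = df["excluded"].astype(bool)
    return df[MEASURES_COLUMNS]
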