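"""From raw pixel streams to analysis-frame trajectories and trial measures.

The analysis frame ("xu" coordinates) places the home-box center at the
origin, flips the vertical axis so motion toward the targets is positive y,
and rescales each axis so the home-to-target displacement is 100 xu
horizontally and 200 xu vertically.  Left-going movements are mirrored at the
vertical midline so every trajectory heads toward the right target.

Per trial we derive three measures:

* **IT** (initiation time): stimulus onset to the first sample strictly
  outside the home rectangle.
* **MT** (movement time): home exit to the first subsequent sample inside a
  20 px circle around the clicked target's center.
* **AUC**: signed area (xu^2) between the time-normalized path and the
  straight chord from its first to its last point; positive when the path
  bulges toward the *non-chosen* target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import GeometryError, ScreenGeometry
from .io import RawTrial

__all__ = [
    "AnalysisPath",
    "NormalizedPath",
    "TrialMeasures",
    "to_analysis_frame",
    "mirror_to_right",
    "segment_movement",
    "time_normalize",
    "compute_auc",
    "measure_trial",
    "measure_session",
    "EXCLUSION_REASONS",
    "N_NORM_POINTS",
]

#: number of interpolated points on the time-normalization grid
N_NORM_POINTS = 101

EXCLUSION_REASONS = (
    "none",
    "error",
    "it_cutoff",
    "mt_cutoff",
    "auc_cutoff",
    "sd_outlier",
    "too_few_points",
    "no_target_entry",
)


@dataclass
class AnalysisPath:
    """A trial's full sample stream in xu analysis coordinates."""

    times: np.ndarray  # (n,) ms on the session clock
    points: np.ndarray  # (n, 2) xu
    mirrored: bool = False
    movement_window: tuple[int, int] | None = None  # (home-exit idx, target-entry idx)


@dataclass
class NormalizedPath:
    """101 time-normalized points plus the appended final coordinate (102 rows)."""

    points: np.ndarray  # (102, 2) xu

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_NORM_POINTS + 1, 2):
            raise ValueError(
                f"normalized path must have {N_NORM_POINTS + 1} points, "
                f"got {self.points.shape}"
            )


@dataclass
class TrialMeasures:
    """Derived measures and validity flags for one trial."""

    participant_id: str
    experiment_id: str
    block: int
    trial_index: int
    category: str
    comparison_type: str
    intention: str
    chosen_option: str
    chosen_innovativeness: str
    it_ms: float
    mt_ms: float
    auc_xu2: float
    n_samples: int
    error: bool
    excluded: bool = False
    exclusion_reason: str = "none"


def to_analysis_frame(trial: RawTrial, geom: ScreenGeometry) -> AnalysisPath:
    """Map raw participant-pixel samples into xu analysis coordinates.

    Divides out the participant's display scale, translates the home center
    to the origin, flips y (screen y grows downward), and rescales so the
    home-to-target span is (100, 200) xu.
    """
    if trial.display_scale <= 0:
        raise GeometryError(f"{trial.key}: display_scale must be positive")
    dx = geom.horizontal_span_px
    dy = geom.vertical_span_px
    if dx <= 0 or dy <= 0:
        raise GeometryError("zero home-to-target distance")
    ref = trial.samples[:, 1:3] / trial.display_scale
    hx, hy = geom.home_center
    pts = np.empty_like(ref)
    pts[:, 0] = (ref[:, 0] - hx) / dx * 100.0
    pts[:, 1] = (hy - ref[:, 1]) / dy * 200.0
    return AnalysisPath(times=trial.samples[:, 0].copy(), points=pts)


def mirror_to_right(path: AnalysisPath, clicked_side: str) -> AnalysisPath:
    """Mirror left-going paths at the vertical midline; right-going unchanged."""
    if clicked_side == "right":
        return path
    pts = path.points.copy()
    pts[:, 0] = -pts[:, 0]
    return replace(path, points=pts, mirrored=not path.mirrored)


def segment_movement(
    trial: RawTrial, geom: ScreenGeometry
) -> tuple[float, float, tuple[int, int] | None, str]:
    """Locate home exit and target entry; return (it_ms, mt_ms, window, reason).

    Home exit is the first sample strictly outside the home rectangle; target
    entry is the first subsequent sample within ``target_entry_radius`` px of
    the clicked target's center.  All geometry is scaled by the trial's
    display scale before comparison.  If either event never occurs the reason
    is ``"no_target_entry"`` and times are NaN.
    """
    s = trial.display_scale
    xy = trial.samples[:, 1:3]
    t = trial.samples[:, 0]
    if len(xy) == 0:
        return np.nan, np.nan, None, "too_few_points"

    hx, hy = (c * s for c in geom.home_center)
    hw, hh = (c * s / 2.0 for c in geom.home_size)
    outside = (np.abs(xy[:, 0] - hx) > hw) | (np.abs(xy[:, 1] - hy) > hh)
    exit_candidates = np.flatnonzero(outside)
    if len(exit_candidates) == 0:
        return np.nan, np.nan, None, "no_target_entry"
    i_exit = int(exit_candidates[0])

    tx, ty = (c * s for c in geom.target_center(trial.clicked_side))
    r = geom.target_entry_radius * s
    d2 = (xy[:, 0] - tx) ** 2 + (xy[:, 1] - ty) ** 2
    entry_candidates = np.flatnonzero(d2[i_exit:] <= r * r)
    if len(entry_candidates) == 0:
        return np.nan, np.nan, None, "no_target_entry"
    i_entry = i_exit + int(entry_candidates[0])

    it_ms = t[i_exit] - trial.onset_ms
    mt_ms = t[i_entry] - t[i_exit]
    return float(it_ms), float(mt_ms), (i_exit, i_entry), "none"


def time_normalize(path: AnalysisPath) -> NormalizedPath:
    """Resample the movement window to 101 equally spaced time points.

    Each grid point is linearly interpolated between the bracketing raw
    samples; grid point 0 is the home-exit sample and grid point 100 the
    target-entry sample.  A 102nd point, the trial's final recorded
    coordinate, is appended to compensate for dwell time inside the target.
    """
    if path.movement_window is None:
        raise ValueError("path has no movement window")
    i0, i1 = path.movement_window
    if i1 - i0 < 1:
        raise ValueError("movement window must span at least 2 samples")
    t = path.times[i0 : i1 + 1]
    pts = path.points[i0 : i1 + 1]
    grid = np.linspace(t[0], t[-1], N_NORM_POINTS)
    out = np.empty((N_NORM_POINTS + 1, 2))
    out[:N_NORM_POINTS, 0] = np.interp(grid, t, pts[:, 0])
    out[:N_NORM_POINTS, 1] = np.interp(grid, t, pts[:, 1])
    out[N_NORM_POINTS] = path.points[-1]
    return NormalizedPath(points=out)


def compute_auc(npath: "NormalizedPath | np.ndarray") -> float:
    """Signed area between the polyline and its start-to-end chord, in xu^2.

    Computed as the shoelace area of the closed polygon formed by the path
    vertices and the straight chord back from endpoint to start — exact for
    polylines.  Orientation is chosen so that area lying to the left of the
    chord direction (toward the non-chosen target, after mirroring) is
    positive.  Accepts a :class:`NormalizedPath` or any ``(n, 2)`` polyline.
    """
    pts = npath.points if isinstance(npath, NormalizedPath) else np.asarray(npath, float)
    if np.allclose(pts[0], pts[-1]):
        warnings.warn("degenerate chord (start == end); AUC set to 0", stacklevel=2)
        return 0.0
    x, y = pts[:, 0], pts[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    # shoelace is positive counterclockwise; a leftward bulge traces the
    # closed loop clockwise, so flip the sign
    return float(-0.5 * np.sum(cross))


def measure_trial(
    trial: RawTrial, geom: ScreenGeometry
) -> tuple[TrialMeasures, NormalizedPath | None]:
    """Run the full per-trial pipeline and return measures plus the path.

    Composition: frame conversion -> movement segmentation -> mirroring ->
    time normalization -> AUC.  The chosen option and error flag are always
    recorded, even when kinematic measures are unavailable, so that choice
    frequencies can be computed over all trials.
    """
    it_ms, mt_ms, window, reason = segment_movement(trial, geom)
    auc = np.nan
    npath = None
    n_window = 0
    if window is not None:
        i0, i1 = window
        n_window = i1 - i0 + 1
        apath = to_analysis_frame(trial, geom)
        apath.movement_window = window
        apath = mirror_to_right(apath, trial.clicked_side)
        if n_window < 3:
            reason = "too_few_points"
        else:
            npath = time_normalize(apath)
            auc = compute_auc(npath)
    measures = TrialMeasures(
        participant_id=trial.participant_id,
        experiment_id=trial.experiment_id,
        block=trial.block,
        trial_index=trial.trial_index,
        category=trial.category,
        comparison_type=trial.comparison_type,
        intention=trial.intention,
        chosen_option=trial.chosen_option,
        chosen_innovativeness=trial.chosen_innovativeness,
        it_ms=it_ms,
        mt_ms=mt_ms,
        auc_xu2=auc,
        n_samples=n_window,
        error=trial.is_error,
        excluded=reason != "none",
        exclusion_reason=reason,
    )
    return measures, npath


def measure_session(
    trials: list[RawTrial], geom: ScreenGeometry
) -> tuple[pd.DataFrame, dict[tuple, NormalizedPath]]:
    """Measure every trial of a session.

    Returns a per-trial measures table (one row per input trial, in input
    order) and a dict of normalized paths keyed by
    ``(participant_id, block, trial_index)`` for trials where one exists.
    """
    rows = []
    paths: dict[tuple, NormalizedPath] = {}
    for trial in trials:
        m, npath = measure_trial(trial, geom)
        rows.append(vars(m))
        if npath is not None:
            paths[trial.key] = npath
    return pd.DataFrame(rows), paths
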