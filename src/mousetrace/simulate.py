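"""Synthetic two-choice mouse-tracking sessions with known ground truth.

The generator emulates the study design end to end: an 800 x 600 reference
screen with a bottom-center home box and upper-left/right targets, five
blocks of forty trials per participant, a 2x2 within-subject structure
(comparison type x chosen-target innovativeness), lognormal initiation and
movement times, and cursor paths built from a minimum-jerk reach along the
home-to-target chord plus a condition-dependent lateral attraction bulge
toward the non-chosen option.

The bulge is sinusoidal in path fraction, so the noiseless signed area it
produces has the closed form 2*beta*L/pi (L = chord length), which makes the
whole AUC pipeline checkable analytically.  Error trials (click contradicts
the declared intention), extreme-outlier trials (beyond the preregistered
cutoffs) and low-validity participants are injected at configurable rates,
and every trial's ground truth (event times, bulge amplitude, injected
flags) is emitted in a sidecar table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry
from .io import TRIALS_COLUMNS, SAMPLES_COLUMNS, write_session

__all__ = [
    "SimConfig",
    "minimum_jerk_path",
    "add_attraction_bulge",
    "generate_session",
    "generate_experiment",
    "CHORD_LENGTH_XU",
]

#: home-to-target chord length in analysis units
CHORD_LENGTH_XU = float(np.hypot(100.0, 200.0))

_OPTION_BY_INNOV = {
    "past": {"high": "contemporary", "low": "historic"},
    "future": {"high": "innovative", "low": "contemporary"},
}

DESIGN_CELLS = (("past", "high"), ("past", "low"), ("future", "high"), ("future", "low"))


@dataclass
class SimConfig:
    """Study-level simulation parameters.

    Defaults reproduce the study conditions: 68 participants, 5 blocks x 40
    trials, balanced comparison types, and a crossover pattern of lateral
    attraction (strong pull toward the non-chosen historic option in past
    comparisons when choosing the innovative one; strong pull toward the
    non-chosen innovative option in future comparisons when choosing the
    traditional one).
    """

    experiment_id: str = "sim"
    n_participants: int = 68
    blocks: int = 5
    trials_per_block: int = 40
    #: lateral attraction amplitude (xu) toward the non-chosen option,
    #: per (comparison_type, chosen innovativeness) cell
    cell_bias: dict = field(
        default_factory=lambda: {
            ("past", "high"): 9.0,
            ("past", "low"): 4.0,
            ("future", "high"): 3.0,
            ("future", "low"): 11.0,
        }
    )
    #: between-participant SD of the per-cell attraction amplitude (xu)
    participant_bias_sd: float = 6.0
    #: trial-to-trial SD of the attraction amplitude (xu)
    trial_bias_sd: float = 2.0
    #: isotropic Gaussian jitter on each movement sample (xu)
    path_noise_sd: float = 1.5
    sample_rate: float = 60.0  # Hz
    #: lognormal (mu, sigma) of initiation time in ms
    it_lognorm: tuple[float, float] = (np.log(500.0), 0.35)
    #: lognormal sigma of movement time; medians are per cell below
    mt_sigma: float = 0.25
    #: nominal home-to-target reach duration medians (ms) per design cell.
    #: The *measured* movement time (home exit to 20-px entry) is ~0.65 of
    #: the nominal duration, since the minimum-jerk reach spends its slow
    #: opening inside the home box and its slow ending inside the entry
    #: circle.  Medians are chosen so measured MTs land near 900 ms, slower
    #: toward the traditional option in future comparisons.
    mt_median_ms: dict = field(
        default_factory=lambda: {
            ("past", "high"): 1410.0,
            ("past", "low"): 1380.0,
            ("future", "high"): 1360.0,
            ("future", "low"): 1550.0,
        }
    )
    #: multiplicative between-participant spread of movement time
    participant_mt_sd_log: float = 0.15
    p_choose_innovative: dict = field(
        default_factory=lambda: {"past": 0.55, "future": 0.50}
    )
    error_rate: float = 0.05
    outlier_rate: float = 0.02
    low_validity_participants: int = 7
    #: outlier rate applied to low-validity participants
    low_validity_outlier_rate: float = 0.85
    display_scale_range: tuple[float, float] = (0.75, 1.5)
    inter_trial_ms: float = 500.0
    seed: int = 0


def minimum_jerk_path(
    duration_ms: float,
    start: tuple[float, float],
    end: tuple[float, float],
    sample_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Straight-chord reach with the minimum-jerk speed profile.

    Position along the chord follows s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5;
    the first sample is exactly at ``start`` and the last exactly at ``end``.
    Returns ``(times_ms, points)``.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    n = max(2, int(round(duration_ms * sample_rate / 1000.0)) + 1)
    times = np.linspace(0.0, duration_ms, n)
    tau = times / duration_ms
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    points = start[None, :] + s[:, None] * (end - start)[None, :]
    return times, points


def add_attraction_bulge(points: np.ndarray, beta: float) -> np.ndarray:
    """Add a lateral sinusoidal bulge of amplitude ``beta`` to a reach path.

    The offset is ``beta * sin(pi * s)`` orthogonal to the start-to-end
    chord, where ``s`` is the path fraction (projection onto the chord).
    Positive ``beta`` displaces the path to the left of the chord direction —
    toward the non-chosen option for a rightward reach in the analysis
    frame.  The noiseless signed area this adds is 2*beta*L/pi.
    """
    points = np.asarray(points, dtype=float)
    chord = points[-1] - points[0]
    L = np.hypot(*chord)
    if L == 0:
        raise ValueError("degenerate chord")
    d = chord / L
    perp = np.array([-d[1], d[0]])  # +90 degrees: left of travel
    s = (points - points[0]) @ d / L
    return points + (beta * np.sin(np.pi * s))[:, None] * perp


def _xu_to_px(points_xu: np.ndarray, geom: ScreenGeometry, scale: float) -> np.ndarray:
    """Inverse of the analysis-frame mapping, at participant display scale."""
    hx, hy = geom.home_center
    out = np.empty_like(points_xu)
    out[:, 0] = (hx + points_xu[:, 0] * geom.horizontal_span_px / 100.0) * scale
    out[:, 1] = (hy - points_xu[:, 1] * geom.vertical_span_px / 200.0) * scale
    return out


def _scan_events(
    samples: np.ndarray, geom: ScreenGeometry, scale: float, side: str
) -> tuple[float, float]:
    """Ground-truth home-exit / target-entry times from a raw sample stream."""
    xy = samples[:, 1:3]
    hx, hy = (c * scale for c in geom.home_center)
    hw, hh = (c * scale / 2.0 for c in geom.home_size)
    outside = (np.abs(xy[:, 0] - hx) > hw) | (np.abs(xy[:, 1] - hy) > hh)
    idx = np.flatnonzero(outside)
    if len(idx) == 0:
        return np.nan, np.nan
    i0 = idx[0]
    tx, ty = (c * scale for c in geom.target_center(side))
    r = geom.target_entry_radius * scale
    inside = (xy[i0:, 0] - tx) ** 2 + (xy[i0:, 1] - ty) ** 2 <= r * r
    jdx = np.flatnonzero(inside)
    if len(jdx) == 0:
        return float(samples[i0, 0]), np.nan
    return float(samples[i0, 0]), float(samples[i0 + jdx[0], 0])


def _simulate_trial(
    rng: np.random.Generator,
    config: SimConfig,
    geom: ScreenGeometry,
    scale: float,
    onset_ms: float,
    ctype: str,
    subj_bias: dict,
    subj_mt_log: float,
    outlier_rate: float,
) -> dict:
    """Simulate one trial; returns metadata, samples and ground truth."""
    dt = 1000.0 / config.sample_rate

    intends_high = rng.random() < config.p_choose_innovative[ctype]
    is_error = rng.random() < config.error_rate
    chooses_high = intends_high != is_error
    innov = "high" if chooses_high else "low"
    chosen = _OPTION_BY_INNOV[ctype][innov]
    other = _OPTION_BY_INNOV[ctype]["low" if chooses_high else "high"]
    side = "left" if rng.random() < 0.5 else "right"

    is_outlier = (not is_error) and rng.random() < outlier_rate
    outlier_kind = rng.choice(["it", "mt", "auc"]) if is_outlier else ""

    it_nominal = rng.lognormal(*config.it_lognorm)
    mt_median = config.mt_median_ms[(ctype, innov)]
    mt_nominal = rng.lognormal(np.log(mt_median) + subj_mt_log, config.mt_sigma)
    beta = (
        config.cell_bias[(ctype, innov)]
        + subj_bias[(ctype, innov)]
        + rng.normal(0.0, config.trial_bias_sd)
    )
    # injected outliers must land beyond the preregistered cutoffs in the
    # *measured* quantities: measured IT exceeds nominal IT, but measured MT
    # is only ~0.65 of the nominal reach duration, hence the 8200 ms floor
    if outlier_kind == "it":
        it_nominal = 3200.0 + rng.exponential(1200.0)
    elif outlier_kind == "mt":
        mt_nominal = 8200.0 + rng.exponential(1500.0)
    elif outlier_kind == "auc":
        beta = 250.0 + rng.exponential(50.0) if rng.random() < 0.5 else -(
            160.0 + rng.exponential(40.0)
        )

    # home half-sizes in xu: jitter must keep pre-movement samples inside
    hw_xu = geom.home_size[0] / 2.0 / geom.horizontal_span_px * 100.0
    hh_xu = geom.home_size[1] / 2.0 / geom.vertical_span_px * 200.0
    jit = 0.25 * min(hw_xu, hh_xu)

    pre_times = np.arange(0.0, it_nominal, dt)
    pre_pts = rng.uniform(-jit, jit, size=(len(pre_times), 2))

    mov_times, mov_pts = minimum_jerk_path(
        mt_nominal, (0.0, 0.0), (100.0, 200.0), config.sample_rate
    )
    mov_pts = add_attraction_bulge(mov_pts, beta)
    mov_pts = mov_pts + rng.normal(0.0, config.path_noise_sd, size=mov_pts.shape)
    mov_pts[0] = (0.0, 0.0)  # reach starts at the home center
    mov_times = mov_times + it_nominal

    dwell_times = mov_times[-1] + dt * np.arange(1, 4)
    dwell_pts = np.array([[100.0, 200.0]] * 3) + rng.normal(0.0, 0.3, size=(3, 2))

    times = np.concatenate([pre_times, mov_times, dwell_times]) + onset_ms
    pts_xu = np.vstack([pre_pts, mov_pts, dwell_pts])
    if side == "left":
        pts_xu = pts_xu.copy()
        pts_xu[:, 0] = -pts_xu[:, 0]
    pts_px = _xu_to_px(pts_xu, geom, scale)
    samples = np.column_stack([times, pts_px])

    t_exit, t_entry = _scan_events(samples, geom, scale, side)
    intention = "more_innovative" if intends_high else "less_innovative"
    return {
        "meta": {
            "category": f"cat{rng.integers(0, 20):02d}",
            "comparison_type": ctype,
            "intention": intention,
            "option_left": chosen if side == "left" else other,
            "option_right": chosen if side == "right" else other,
            "clicked_side": side,
            "onset_ms": onset_ms,
            "display_scale": scale,
        },
        "samples": samples,
        "truth": {
            "comparison_type": ctype,
            "chosen_innovativeness": innov,
            "beta_xu": float(beta),
            "t_exit_ms": t_exit,
            "t_entry_ms": t_entry,
            "it_ms": t_exit - onset_ms if np.isfinite(t_exit) else np.nan,
            "mt_ms": t_entry - t_exit if np.isfinite(t_entry) else np.nan,
            "is_error": is_error,
            "is_outlier": is_outlier,
            "outlier_kind": outlier_kind,
        },
        "end_ms": float(times[-1]),
    }


def _simulate_all(config: SimConfig, geom: ScreenGeometry):
    """Yield (key, meta, samples, truth_row) for every trial, in order."""
    children = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    for p in range(config.n_participants):
        rng = np.random.default_rng(children[p])
        pid = f"p{p:03d}"
        low_validity = p < config.low_validity_participants
        outlier_rate = (
            config.low_validity_outlier_rate if low_validity else config.outlier_rate
        )
        scale = rng.uniform(*config.display_scale_range)
        subj_bias = {
            cell: rng.normal(0.0, config.participant_bias_sd) for cell in DESIGN_CELLS
        }
        subj_mt_log = rng.normal(0.0, config.participant_mt_sd_log)
        clock = 0.0
        for b in range(1, config.blocks + 1):
            half = config.trials_per_block // 2
            ctypes = ["past"] * half + ["future"] * (config.trials_per_block - half)
            rng.shuffle(ctypes)
            for i, ctype in enumerate(ctypes, start=1):
                sim = _simulate_trial(
                    rng, config, geom, scale, clock, ctype,
                    subj_bias, subj_mt_log, outlier_rate,
                )
                key = {"participant_id": pid, "block": b, "trial_index": i}
                truth_row = {**key, "is_low_validity": low_validity, **sim["truth"]}
                yield key, sim["meta"], sim["samples"], truth_row
                clock = sim["end_ms"] + config.inter_trial_ms


def generate_raw_trials(config: SimConfig, geom: ScreenGeometry | None = None):
    """Generate RawTrial objects directly, skipping the tabular round-trip.

    Returns ``(trials, truth)`` where ``trials`` is a list of
    :class:`~mousetrace.io.RawTrial` and ``truth`` the ground-truth
    DataFrame.  Draws are identical to :func:`generate_session` for the
    same config.
    """
    from .io import RawTrial

    if geom is None:
        geom = ScreenGeometry()
    trials = []
    truth_rows = []
    for key, meta, samples, truth_row in _simulate_all(config, geom):
        trials.append(
            RawTrial(
                participant_id=key["participant_id"],
                experiment_id=config.experiment_id,
                block=key["block"],
                trial_index=key["trial_index"],
                category=meta["category"],
                comparison_type=meta["comparison_type"],
                intention=meta["intention"],
                option_left=meta["option_left"],
                option_right=meta["option_right"],
                clicked_side=meta["clicked_side"],
                onset_ms=meta["onset_ms"],
                display_scale=meta["display_scale"],
                samples=samples,
            )
        )
        truth_rows.append(truth_row)
    return trials, pd.DataFrame(truth_rows)


def generate_session(
    config: SimConfig, geom: ScreenGeometry | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic session.

    Returns ``(trials, samples, truth)`` DataFrames in the canonical schema.
    Output is a pure function of ``config`` (including its seed): each
    participant draws from a deterministic substream, so the same seed gives
    byte-identical files.
    """
    if geom is None:
        geom = ScreenGeometry()
    trial_rows = []
    arrays = []
    keys = []
    truth_rows = []
    for key, meta, samples, truth_row in _simulate_all(config, geom):
        trial_rows.append({**key, "experiment_id": config.experiment_id, **meta})
        arrays.append(samples)
        keys.append((key["participant_id"], key["block"], key["trial_index"]))
        truth_rows.append(truth_row)

    trials = pd.DataFrame(trial_rows)[TRIALS_COLUMNS]
    counts = np.array([len(a) for a in arrays])
    stacked = np.concatenate(arrays, axis=0)
    samples = pd.DataFrame(
        {
            "participant_id": np.repeat([k[0] for k in keys], counts),
            "block": np.repeat([k[1] for k in keys], counts),
            "trial_index": np.repeat([k[2] for k in keys], counts),
            "t_ms": stacked[:, 0],
            "x_px": stacked[:, 1],
            "y_px": stacked[:, 2],
        }
    )[SAMPLES_COLUMNS]
    truth = pd.DataFrame(truth_rows)
    return trials, samples, truth


def generate_experiment(config: SimConfig, out_dir, geom: ScreenGeometry | None = None):
    """Generate a session and write trials.csv, samples.csv and truth.json."""
    out_dir = Path(out_dir)
    trials, samples, truth = generate_session(config, geom)
    write_session(trials, samples, out_dir)
    truth_records = json.loads(truth.to_json(orient="records"))
    (out_dir / "truth.json").write_text(json.dumps(truth_records, indent=1))
    return trials, samples, truth
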