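import numpy as np
import pandas as pd
import pytest

from mousetrace import RawTrial, ScreenGeometry, SimConfig
from mousetrace.simulate import generate_raw_trials


@pytest.fixture(scope="session")
def geom() -> ScreenGeometry:
    return ScreenGeometry()


def make_trial(
    samples,
    clicked_side="right",
    comparison_type="past",
    intention="more_innovative",
    chosen="contemporary",
    onset_ms=0.0,
    display_scale=1.0,
    participant_id="p000",
    block=1,
    trial_index=1,
) -> RawTrial:
    """Hand-build a trial; the chosen option sits on the clicked side."""
    pair = {"past": ("historic", "contemporary"), "future": ("contemporary", "innovative")}
    other = next(o for o in pair[comparison_type] if o != chosen)
    left, right = (chosen, other) if clicked_side == "left" else (other, chosen)
    return RawTrial(
        participant_id=participant_id,
        experiment_id="test",
        block=block,
        trial_index=trial_index,
        category="cat00",
        comparison_type=comparison_type,
        intention=intention,
        option_left=left,
        option_right=right,
        clicked_side=clicked_side,
        onset_ms=onset_ms,
        display_scale=display_scale,
        samples=np.asarray(samples, dtype=float),
    )


def straight_reach(geom: ScreenGeometry, side="right", n=60, it_ms=400.0, mt_ms=800.0,
                   scale=1.0, onset_ms=0.0, **kwargs) -> RawTrial:
    """A clean straight home-to-target reach sampled uniformly in time."""
    hx, hy = geom.home_center
    tx, ty = geom.target_center(side)
    pre_t = np.arange(0.0, it_ms, 1000.0 / 60)
    pre = np.column_stack([pre_t, np.full_like(pre_t, hx), np.full_like(pre_t, hy)])
    frac = np.linspace(0.0, 1.0, n)
    mov_t = it_ms + frac * mt_ms
    mov = np.column_stack([mov_t, hx + frac * (tx - hx), hy + frac * (ty - hy)])
    stream = np.vstack([pre, mov])
    stream[:, 0] += onset_ms
    stream[:, 1:] *= scale
    return make_trial(stream, clicked_side=side, display_scale=scale,
                      onset_ms=onset_ms, **kwargs)


def measures_frame(rows) -> pd.DataFrame:
    """Minimal measures table for exclusion-module tests."""
    defaults = dict(
        participant_id="p000",
        experiment_id="test",
        block=1,
        trial_index=1,
        category="cat00",
        comparison_type="past",
        intention="more_innovative",
        chosen_option="contemporary",
        chosen_innovativeness="high",
        it_ms=500.0,
        mt_ms=900.0,
        auc_xu2=1000.0,
        n_samples=50,
        error=False,
        excluded=False,
        exclusion_reason="none",
    )
    out = []
    for i, row in enumerate(rows):
        r = {**defaults, "trial_index": i + 1, **row}
        out.append(r)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def small_session(geom):
    """A small but complete synthetic session shared across tests."""
    cfg = SimConfig(
        n_participants=6,
        blocks=2,
        trials_per_block=40,
        low_validity_participants=1,
        seed=42,
    )
    trials, truth = generate_raw_trials(cfg, geom)
    return cfg, trials, truth
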