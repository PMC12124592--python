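# mousetrace

Action-dynamics analysis of two-choice mouse-cursor experiments.

In mouse-tracking ("process tracing") studies, participants choose between
two options shown in the upper-left and upper-right of the screen by moving
the cursor from a home box at the bottom center to one of the targets. The
kinematics of that reach carry information the final click does not: a
trajectory that bends toward the option the participant did *not* choose
indicates that the rejected option attracted the response in flight.
`mousetrace` implements the full analysis chain for a 2x2 within-subject
design of this kind — comparison type (a *past* pair: historic vs
contemporary option, or a *future* pair: contemporary vs innovative option)
crossed with the relative innovativeness of the chosen target — from raw
cursor logs to the statistical report, plus a synthetic session generator
with known ground truth so every stage is testable without behavioral data.

## Measures

For every trial, with screen coordinates rescaled so the home-to-target
displacement is 100 x-units (xu) horizontally and 200 xu vertically, and
left-going movements mirrored to the right:

- **IT** (initiation time): stimulus onset to the first sample strictly
  outside the 60 x 60 px home box.
- **MT** (movement time): home exit to the first sample inside a 20 px
  circle around the clicked target's center.
- **AUC** (xu²): signed area between the time-normalized trajectory
  (101 points plus the appended final coordinate) and the straight chord
  from its start to its end; positive when the path bulges toward the
  non-chosen option.

Preregistered exclusions are applied as a fixed cascade: error trials
(click contradicts the declared intention), absolute cutoffs
(IT > 3000 ms, MT > 5000 ms, AUC > 30000 or < −20000 xu²), trials with
fewer than 3 movement samples, a single-pass 2.5-SD filter around each
participant-by-cell mean, and finally participants with fewer than 10 valid
trials in any design cell. Choice frequencies always use all trials.

Inference is within-subject throughout: paired t-tests on per-participant
choice counts, 2x2 repeated-measures ANOVAs (F(1, n−1), partial η² =
F/(F+df₂)) on cell means of IT/MT/AUC, interaction-gated follow-up paired
t-tests, Cohen's d_z = t/√n with 95% confidence intervals from the
noncentral-t pivot, and an exact noncentral-t power solver for the paired
t-test (`power_paired_t`, `required_n`, `minimal_detectable_dz`).

## Worked example

Simulate a full-scale study (68 participants, 5 blocks x 40 trials, 7
low-validity participants, crossover attraction biases), analyze it, and
print the report:

```sh
mousetrace simulate --out demo/session --seed 7
mousetrace analyze --trials demo/session/trials.csv \
    --samples demo/session/samples.csv --out demo/reports
mousetrace report --in demo/reports
```

```
participants: 61 included / 68 total
trials excluded: 2599 of 13600
  error: 723
  it_cutoff: 489
  mt_cutoff: 435
  auc_cutoff: 457
  sd_outlier: 495
...
auc comparison: F(1, 60) = 7.54, p = 0.008, eta_p2 = 0.11
auc innovativeness: F(1, 60) = 0.19, p = 0.666, eta_p2 = 0.00
auc interaction: F(1, 60) = 62.13, p = 0.000, eta_p2 = 0.51
auc follow-up (past): t(60) = 5.66, p = 0.000, dz = 0.73 95%-CI [0.44, 1.01]
auc follow-up (future): t(60) = -5.61, p = 0.000, dz = -0.72 95%-CI [-1.00, -0.43]
```

The seven injected low-validity participants fail the 10-valid-trials-
per-cell criterion (61 of 68 included). The AUC interaction is the
signature result pattern: in past comparisons trajectories are pulled
toward the historic option when the innovative one is chosen (positive
d_z), while in future comparisons the pull reverses toward the innovative
option (negative d_z). Follow-up t-tests are only evaluated when the
interaction is significant at α = .05.

The same objects are available as a library:

```python
from mousetrace import SimConfig, PipelineConfig, run_pipeline, required_n

result = run_pipeline(PipelineConfig(simulation=SimConfig(seed=7)))
result["stats_report"]["measures"]["auc"]["anova"]
required_n(dz=0.40, power=0.80, alpha=0.05)   # -> 51
```

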