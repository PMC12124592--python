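# Methods

## Coordinate frames and trajectory measures

Raw cursor samples arrive in the participant's native pixel frame
(y grows downward) at an arbitrary display scale. Analysis happens in a
normalized frame: the home-box center maps to the origin, the vertical
axis is flipped so motion toward the targets is positive, and each axis is
rescaled so the home-to-target displacement is (100, 200) xu. Scaling by
any positive display factor is therefore exactly neutral (a tested
invariant). Left-going reaches are mirrored at the vertical midline after
frame conversion, so all paths head to the right target.

Movement segmentation uses two different geometric events on purpose: home
exit is the first sample *strictly outside the home rectangle*, while
target entry is the first subsequent sample *inside a 20 px circle* around
the clicked target's center (both scaled by the trial's display factor).
IT is onset-to-exit, MT exit-to-entry. Trials whose cursor never leaves
home or never enters the circle have no kinematic measures; they keep
their click and still count for choice frequencies.

Time normalization resamples the movement window at 101 equally spaced
times between the exit and entry samples by linear interpolation, with
both endpoints on the grid; the trial's final recorded coordinate is
appended as a 102nd point to absorb variable dwell inside the target.
Interpolation is exact on paths that are linear between grid times.

AUC is the signed area between the normalized polyline and the straight
chord from its first to its last point, computed by the shoelace formula
on the closed polygon — exact for polylines, no projection or quadrature
error. The sign convention puts area to the left of the chord direction
(toward the non-chosen target, after mirroring) positive, so attraction
toward the rejected option yields positive AUC. This orientation is also
what makes the asymmetric absolute cutoffs (+30000 / −20000 xu²)
meaningful: pulls toward the rejected option are the phenomenon and get
the wider band.

## Exclusion cascade

Order is fixed and each trial receives exactly one reason, from the first
stage that fires:

1. error trials (click contradicts the declared intention);
2. unmeasurable movement (`no_target_entry`) — placed here because the
   later stages need finite measures;
3. absolute cutoffs, strict inequalities: IT > 3000 ms, MT > 5000 ms,
   AUC > 30000 xu², AUC < −20000 xu²;
4. fewer than 3 samples in the movement window (no meaningful AUC);
5. 2.5-SD filter per participant x comparison-type x innovativeness cell,
   per measure, **single pass**: cell means and SDs are computed once on
   the trials surviving stages 1–4 and not recomputed after removals.
   A trial flagged on any one measure is invalid for all measures (one
   validity flag per trial). Cells with fewer than two surviving trials
   have no defined SD; they are skipped and logged on the report.
6. participants with fewer than 10 valid trials in any of the four design
   cells are removed from performance analyses only.

The "cell" of the SD filter is the by-participant design cell, consistent
with the purely within-subject analyses; a pooled-cell reading would mix
participants with different baselines. Re-running the cascade on filtered
data changes nothing except possibly the SD filter, which is single-pass
by definition.

## Inference

All tests are two-tailed. The 2x2 repeated-measures ANOVA is fitted by
`pingouin.rm_anova`; with single-df effects every F equals the square of
the paired t on the corresponding difference scores, an identity the test
suite checks against this package's own t-test implementation (two
independent routes). Partial η² is derived as F/(F + df₂).

Effect sizes are Cohen's d_z = mean(diff)/SD(diff) = t/√n. Confidence
intervals use the noncentral-t pivot: the bounds are the noncentrality
parameters whose noncentral-t distributions leave 2.5% of probability
beyond the observed t, divided by √n. Inversion is by bracketed root
finding on the (strictly decreasing) CDF-in-ncp to 1e-10; scipy's `nct`
underflows to NaN deep in the tails, which is mapped to the correct limit
(0 or 1). The pivot reproduces the one fully printed interval in the
design literature this package targets ([−0.01, 0.47] at t = 1.93,
n = 68, to 2 dp); no other CI method was tried.

Power for the paired/one-sample t-test is exact noncentral-t power,
power(n, d_z) = P(|T′| > t_crit) with T′ ~ t(n−1, ncp = d_z·√n). The
sample-size solver inverts the continuous-n equation by root finding —
the same arithmetic as R's `power.t.test` — and rounds to the nearest
integer; at d_z = 0.40, α = .05, power = .80 the continuous solution is
51.0096, reported as 51 (exact power at n = 51 is 0.79992, short of 0.80
by 8e-5, i.e. beyond the resolution at which power targets are stated).
Minimal detectable effect sizes solve the same equation for d_z and are
*reported truncated* to two decimals, the convention evident in the
four printed per-cohort values (0.3646/0.3776/0.3847/0.3921 →
0.36/0.37/0.38/0.39; ordinary rounding would print 0.38 for the second).

Follow-up t-tests are computed only when the interaction is significant
at α = .05 (the pipeline enforces this gate), and no multiple-testing
correction is applied anywhere. Degenerate inputs (zero-variance
differences, e.g. unanimous choices) raise an explicit error rather than
returning an infinite t.

Choice-frequency tests use per-participant counts of more- minus
less-innovative clicks over *all* trials of a comparison type; a paired t
on the two counts, which is identical to a one-sample t of the difference
against zero.

## Synthetic sessions

The generator emulates the study conditions: 68 participants, 5 blocks x
40 trials, balanced comparison types within block, randomized
option-to-side mapping, per-participant display scales drawn from
[0.75, 1.5], a 60 Hz sample clock, and one millisecond clock per session
shared by onsets and samples. Each participant draws from a deterministic
substream of the seed, so output is byte-identical across runs.

A reach is a minimum-jerk profile s(τ) = 10τ³ − 15τ⁴ + 6τ⁵ along the
home-to-target chord, plus a lateral attraction bulge β·sin(πs) orthogonal
to the chord (positive β toward the non-chosen option), plus isotropic
Gaussian sample noise (default 1.5 xu). The bulge has closed-form signed
area 2βL/π (L = chord length ≈ 223.6 xu), which anchors the analytic
checks of the AUC engine. Default cell biases form a crossover —
past: β = 9 (innovative chosen) vs 4 xu; future: 3 vs 11 xu — with
between-participant bias SD 6 xu and trial-to-trial SD 2 xu, inducing
follow-up effect sizes around |d_z| ≈ 0.6–0.9 at full scale, the range
this design is powered for. Nominal IT and reach durations are lognormal;
because the minimum-jerk reach opens inside the home box and ends inside
the entry circle, the *measured* MT is ~0.65 of the nominal duration and
the measured AUC of a windowed path is a stable ~0.84 of 2βL/π (the
clipped slow ends carry ~16% of the bulge area). Nominal medians are set
so measured MTs land near 900 ms.

Injected artifacts: error trials (click flipped against the stated
intention) at rate 0.05; extreme outliers at rate 0.02 (mutually exclusive
with errors), each drawn to exceed a specific preregistered cutoff in the
*measured* quantity with margin, so the exclusion report's stage counts
reproduce the injected counts exactly; and 7 "low-validity" participants
whose outlier rate is 0.85, guaranteeing failure of the 10-per-cell
inclusion criterion (68 → 61 included, the first experiment's cohort
arithmetic). Ground-truth home-exit and target-entry times are recorded
per trial by scanning the generated stream with the segmentation rule at
generation time; the pipeline must reproduce them exactly, which exercises
the display-scale handling end to end.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data:

- no between-participant heterogeneity in choice preference: choices are
  i.i.d. Bernoulli within participant, so simulated choice-frequency
  effect sizes are far larger than typical empirical ones whenever
  p ≠ 0.5;
- measured ITs inherit a small condition effect through the home-exit lag
  (which scales with the cell's reach duration), whereas empirical ITs in
  this paradigm typically show none;
- MT condition effects at the default medians come out stronger than the
  empirical range;
- no x-flips, hesitations, pauses, or curvature families beyond a single
  sinusoidal bulge; no item (stimulus-category) random effects — category
  labels are opaque tokens.

## Simulation scales used by the test suite

Calibration tests run at desk scale, chosen to keep the default suite in
a few minutes while leaving the statistical checks well-powered: type-I
error of the interaction test and coverage of the d_z interval use 2000
summary-level simulations each (n = 20 participants); crossover sign
recovery uses 200 full pipeline runs at 20 participants x 2 blocks with
the default biases; the F = t² identity uses 1000 random 2x2 tables. The
acceptance script's quantities are deterministic and run in about a
second.

## Known limitations

- The SD filter is single-pass by specification; iterated filtering would
  exclude slightly more trials.
- `rm_anova_2x2` is restricted to the complete-cell 2x2 within design;
  participants missing a cell are dropped (with a warning), matching
  denominator dfs of n−1.
- The pivot CI assumes the t statistic arises from i.i.d. normal
  differences; coverage under heavy-tailed differences is not studied
  here.
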