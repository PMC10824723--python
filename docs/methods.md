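# Methods

This note documents the statistical model behind `ppspace`, the choices the
implementation makes where the method leaves room, and what the synthetic
validation does and does not establish.

## The measurement model

The pipeline treats the visuo-tactile detection experiment as producing, for
each participant and condition, reaction times RT(x) at five fixed distances
x ∈ {0.25, 0.75, 1.25, 1.75, 2.25} m of the looming stimulus at vibration
onset. Mean RT is assumed to rise sigmoidally from a near-space floor to a
far-space ceiling; the inflection point x_c of that transition is the
peripersonal-space boundary. The group-level estimate proceeds as
filter → screen → pool → normalize → fit:

- **Filtering.** Missed and premature responses are removed first, then RTs
  strictly below 0.100 s or above 1.000 s (boundary values are kept — the
  window rules are strict inequalities), then RTs deviating more than
  `sd_cutoff` (default 3) sample standard deviations (n−1 denominator) from
  their participant-by-distance mean. The SD statistics are computed once on
  the window survivors — a single pass, no re-iteration — which makes
  filtering idempotent by construction. A cell with fewer than two surviving
  trials has no defined SD; the rule is skipped there with a warning. Nothing
  is imputed or replaced.
- **Screening.** Facilitation predicts a positive RT-distance slope.
  Per participant, the five baseline distance-level mean RTs are fit by OLS
  (a trial-level variant exists behind a flag). Participants with both
  R² < 0.1 and slope < 0.005 s/m are excluded from *all* conditions; the
  thresholds are taken as fixed cut-offs rather than re-derived by
  clustering. Pearson's r between R² and slope is reported over the whole
  cohort, before exclusion. Slopes are in s/m — the 0.005 threshold only has
  plausible magnitude if RT is expressed in seconds.
- **Pooling and normalization.** Central-launcher test trials of included
  participants are pooled at the trial level (participants with more
  surviving trials weigh more; a participant-mean variant exists behind a
  flag). The five pooled means are min-max normalized to [0, 1].
  Normalization is exact at the endpoints and idempotent; a flat profile
  (all means equal) is an error, not a silent degenerate fit.
- **Boundary fit.** The normalized profile is fit by bounded nonlinear least
  squares with the logistic y(x) = 1/(1 + e^{−(x − x_c)/b}) — the general
  four-parameter sigmoid with its asymptotes anchored at 0 and 1, which is
  how "anchoring the curve between 0 and 1" is interpreted here (a variant
  with asymptotes free in [0, 1] is available). x_c is constrained to the
  measured range [0.25, 2.25] m; b to [0.01, 5] m, the lower bound preventing
  numerical collapse to a step function. The solver multi-starts from the
  five design distances (width start 0.3 m) and keeps the best-RSS solution,
  ties broken toward the smallest x_c. For the anchored logistic the point of
  maximum slope is x_c itself, and y(x_c) = (y_min + y_max)/2 identically.
  Non-convergence is surfaced in the result, never patched.
- **Inference.** Each condition is bootstrapped independently: 12,000
  iterations by default, each drawing, within every distance stratum,
  round(total/5) trials with replacement — the balanced design keeps every
  resampled dataset the size of the original while representing each
  distance equally. Normalization is recomputed inside every iteration from
  that iteration's resampled means. Per-iteration seeds are spawned
  deterministically from the master seed, so a distribution is reproducible
  from one integer. Failed fits are counted and skipped (never imputed); more
  than 10% failures attaches a warning. Two conditions are compared by
  pairing iterations by index (a convention — the conditions are resampled
  independently) and computing the two-sided sign-test estimate
  p = 2·min(P(Δ ≤ 0), P(Δ ≥ 0)); with all differences on one side the
  estimate is 0 and is displayed as p < 1/n. A Studentized
  normal-approximation variant (`method="t"`) is provided; the sign estimator
  is the default because it is fully determined by the two sample vectors.

### Numerical notes

The bootstrap solves tens of thousands of five-point logistic fits, so the
default engine vectorizes them: a coarse (x_c, log b) grid seeds a damped,
bound-projected Gauss-Newton refinement across all iterations at once, with
the grid solution kept wherever refinement does not improve the residual. A
scalar engine that loops the multi-start scipy solver over the same profiles
is retained (`engine="scalar"`), and the test suite pins the two to each
other at 1e-5; observed agreement is ~1e-9. Batch fitting makes a
1,000-iteration bootstrap run in ~0.3 s, which is what keeps the
calibration experiments below practical.

## The synthetic generator

`ppspace.simulate` emulates the features of the real task that the analysis
depends on: five distances with 20 (or 15) repetitions each, exactly 80%
central launches per distance (deterministic allocation, so pooling retains
exactly 16 — or 12 — trials per distance per participant), 15 catch trials
of each type, and per-trial RT = logistic mean + Gaussian noise truncated at
zero (a lognormal option is not provided; truncation at these means and SDs
is inert in practice). Defaults, chosen once as field-typical values:

| parameter | default | rationale |
|---|---|---|
| RT floor | 0.25 s (SD 0.015 across participants) | near-space mean RT of the task |
| floor→ceiling range | 0.06 s (SD 0.01) | observed 0.25–0.31 s RT span |
| boundary x_c | 1.26 m (SD 0.10) | baseline boundary scale; SD is plausible inter-individual spread |
| width b | 0.30 m (SD 0.05) | transition clearly visible across 2 m of distance |
| trial noise SD | 0.05 s | typical simple-RT trial variability |
| lapse / premature rate | 0.002 each | "occasional"; keeps total removals under ~1% |
| non-responders | flat mean 0.28 s, same noise | the excluded flat/noisy cluster |

Condition effects are planted as additive shifts of each responder's
generative x_c (clipped to the distance range); all other profile fields are
shared across conditions.

What the generator does *not* emulate: sequential effects (fatigue,
learning), lognormal RT tails, response to the visual stimulus itself,
participant-specific lapse structure, or any kinematics of the training
tasks — training conditions exist only through their hypothesized boundary
shift. Passing the synthetic validation therefore shows the *pipeline*
recovers what it assumes; it does not validate those assumptions against
real behavior.

## What the validation shows

With the defaults above at the standard scale (33 responders), the
point-estimate x_c recovers a planted 1.26 m boundary within ±0.05 m (median
over seeds), the null rejection rate of the sign test at α = 0.05 is inside
[0.02, 0.08] over 200 replicate experiments, and a planted +0.32 m effect is
detected in ≥ 15/20 seeds at 1,000 bootstrap iterations per condition.

Two estimator properties surfaced by the simulations are worth knowing:

- **Far-edge compression.** The min-max anchoring treats the sampled minimum
  and maximum mean as the asymptotes. When the true curve has not saturated
  by 2.25 m — as after a large boundary shift — normalization stretches the
  top of the curve and pulls the fitted inflection inward. A generative
  +0.32 m shift from 1.26 m is estimated as ≈ +0.25 m. Comparisons between
  conditions measured by the same estimator remain valid; absolute shifts
  near the edges of the distance range are conservative.
- **Limits of the screening rule.** The exclusion corner (R² < 0.1 ∧
  slope < 0.005 s/m) cannot classify flat participants perfectly under
  realistic noise: with 16 trials per distance and 0.05 s trial SD, a truly
  flat participant's fitted slope is ~N(0, 0.008 s/m), and the R² of a
  5-point fit to a flat truth follows Beta(1/2, 3/2) *regardless of the
  noise scale*, so only ~30% of flat participants land in the corner on any
  given measurement. Conversely a genuine responder whose boundary lies near
  the far end of the distance range is observationally near-flat and can be
  excluded. The rule is a pragmatic screen, not a consistent classifier; the
  test suite asserts the exact-separation property and documents its failure
  rather than weakening it.

## Problem sizes

The test suite and the acceptance script run everything at the scale stated
above (cohorts of 33–41, 1,000–2,000 bootstrap iterations, 200 replicate
null experiments); the full 12,000-iteration default remains the library
default for real analyses.

## Known limitations

- The loader targets this package's CSV schema; adapters from other lab
  formats are the user's responsibility.
- Group-level fits only; per-participant sigmoid fits are deliberately out
  of scope (five points with two free parameters is fragile at the
  individual level).
- The sign-test p-value has resolution 2/n_iterations; report it with its
  floor when no paired difference crosses zero.
- No BCa or studentized-interval machinery; the central 95% interval is the
  only interval reported.
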