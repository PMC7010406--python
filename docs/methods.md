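# Methods

## The task model

Two tasks share one apparatus: five circular touch targets in a horizontal
row (default centers at x = 0, 100, 200, 300, 400 screen units, y = 0;
acceptance radius — "half-width" — 30 units, so targets never overlap
because inter-center spacing must exceed twice the radius). Target IDs run
1–5 left to right.

* **Random task** — the next target is drawn uniformly from the four
  targets other than the one just hit, 100 ms after the previous correct
  touch. The draw excludes the just-hit target because a repeat would
  define a zero-length movement, and all analyses are per movement (ordered
  target pair). The scheduler is an i.i.d. uniform draw from a seeded
  `numpy` generator; the cue stream is reproducible bit-for-bit from the
  seed.
* **Repeating task** — targets follow a fixed three-element sequence
  (presets use 5-3-1 and 1-2-4) cued 400 ms after the previous correct
  touch; the delay leaves room for anticipatory (predictive) responses.

In both tasks the subject must touch the cued target within 800 ms of cue
onset; touches *before* cue onset are valid (anticipations). After an
error or a miss the same target is cued again. The first trial of a block
cues the first sequence element (Repeating) or a seeded draw (Random).
Reward scheduling and tone feedback have no behavioral consequence in the
engine and are not modeled.

## The generative agent

Each movement has parameters (defaults in parentheses):

| parameter | meaning | default |
|---|---|---|
| `p_predictive` | probability of a memory-guided (predictive) response in the Repeating task | 0 |
| `rt_predictive` | (location, scale) of the predictive truncated-normal RT, ms | (50, 60) |
| `rt_cued` | (location, scale) of the cue-guided RT, ms | (350, 90) |
| `mt` | (location, scale) of movement time, ms | (160, 30) |
| `endpoint_sigma` | isotropic endpoint scatter, screen units | 12 |
| `undershoot_bias` | signed displacement along the movement direction (negative = undershoot) | 0 |
| `p_direction_error` | probability the aim is replaced by the nearest target on the opposite side of the origin | 0 |
| `p_no_hit` | probability of no response within the window | 0.005 |
| `dwell_ms` | minimum hold time before release | 0 |

RT distributions are truncated normals: predictive support is
(−cue_delay + 1 ms, 149 ms) and cued support (151 ms, 799 ms), one
millisecond inside the defining boundaries so that rounding touch times to
integer milliseconds can never flip a generated predictive response across
the 150 ms threshold or push a cued response outside the window. The task
description fixes only the 150 ms cutoff and the mean shifts; the component
shapes are this package's modeling choice. Touch times are
`cue_onset + RT` rounded to integer ms; coordinates are rounded to two
decimals (the log format's precision) before endpoint assignment, so
simulation and re-analysis of a written log agree exactly. Release times
are `touch − MT` clipped so release never precedes the previous touch.
Agents respond in the Random task with a small anticipation rate
(`p_fast_random`, default 0.02) whose aim is a uniform guess — these trials
are excluded downstream by the fast-Random rule.

Endpoints are `center(aim) + bias·û + σ·N(0, I₂)` with û the unit vector
from origin to aim. Accuracy errors are therefore *emergent* from bias and
scatter, never drawn from a labeled error distribution; the direction-error
branch is skipped (normal aim retained) when no opposite-side target
exists, which cannot occur for the preset sequences. Because targets are
disjoint, the exact per-movement correct probability has the closed form
P(‖Z‖ ≤ r) for an offset isotropic Gaussian — a noncentral χ² with 2 df —
exposed as `expected_correct_prob` and recorded in the ground-truth sidecar
for non-circular recovery tests.

Injection effects are deltas on generative parameters (subtractive on
`p_predictive`, multiplicative on σ, additive otherwise), applied per
phase/scope: anisomycin shifts Repeating-task movements only, muscimol both
tasks, saline nothing (enforced by validation). Deltas act on parameters,
not on derived statistics.

## Preset calibration

The `anisomycin_session2_N` preset reproduces, in expectation, the showcase
session's summary statistics:

* Pre-injection σ solves P(inside | σ, zero bias) for the observed correct
  rates: σ = 11.824 (96% correct) by default and σ = 13.009 (93%) on
  movement 2→4.
* Post-injection movement 1→5: σ × 1.4 with undershoot −22.14 units, the
  root of P(inside) = 0.55, making ~45% of reaches accuracy errors that
  land short of the target. Movement 2→4 gains `p_direction_error` = 0.18.
  Movement 3→1 keeps its baseline error rate; 1→2 is moderately affected;
  other movements get default deltas (σ × 1.8, bias −12, +0.02 direction).
  Base rates for movements without reported values are interpolations,
  flagged as such here and recoverable from the sidecar.
* Predictive responding drops 0.924 → 0.353 on every sequence movement.
* The cued-RT location delta is −66.39 ms: the observed mean RT over
  included correct trials is a predictive/cued mixture, and the collapse of
  the predictive fraction alone over-shifts that mixture, so the calibrated
  component delta that reproduces the observed +140.23 ms net increase is
  negative. The MT delta is +45.82 ms directly (truncation is negligible
  there).

The muscimol preset is an indiscriminate both-task deficit and the saline
preset an explicit null; their magnitudes are plausible choices, not fits.

## Analysis conventions

* Endpoint assignment is nearest-center, ties toward the lower target ID;
  touches between targets count toward the closest target, but CORRECT
  requires landing inside the correct target's radius.
* Direction is judged on the horizontal axis only (the targets form a
  row); zero horizontal displacement, including re-touches of the origin,
  is OTHER_ERROR since the accuracy/direction dichotomy does not cover it.
* CORRECTIVE relabeling looks back exactly one trial (the erroneous trial
  is repeated immediately) and is applied before exclusions. A correct
  response after a *no-hit* is also treated as corrective — the repeated
  target is equally predictable — which the task description implies but
  does not state.
* Exclusions: corrective responses, no-hit trials, Random-task trials with
  RT < 150 ms. Additionally, the first trial of each block and zero-length
  reaches (hand already on the cued target after an error) have no defined
  movement and are excluded from movement analyses; when several reasons
  apply the recorded reason follows the order corrective → no-hit →
  fast-Random → no-movement.
* Mean RT/MT and the t-test samples cover included correct responses;
  error-rate denominators are all included trials; the predictive-rate
  denominator is included correct responses (predictive and non-predictive
  are subclasses of correct). Error rate per included trial and per
  (correct + error) coincide under these definitions.
* χ² is Pearson without continuity correction (df = 1 throughout; Yates is
  config-exposed), t-tests are Welch (pooling config-exposed) on per-trial
  values, all tests two-sided. The Holm family is the set of movements
  within one test kind × one task × one session. Tests with a zero margin
  or degenerate samples are reported explicitly as not-computable, never
  silently dropped, and do not enter the Holm family.
* Strongest/weakest-movement selection uses the Repeating-task error-rate
  increase; ties break toward the earlier movement in sequence order.
  Population aggregates are mean ± SE across sessions with paired t-tests
  on post−pre differences. Note that selecting the maximal increase
  inflates the type-I error of the strongest-movement paired test under
  the null; the package characterizes but does not correct this, matching
  the analysis it reimplements.

## What the simulator does and does not emulate

It emulates: alternating Random/Repeating blocks (lengths uniform in a
configurable 200–500 range), up to thousands of trials per session,
error-trial repetition, predictive/cued response mixtures, endpoint noise
producing accuracy errors, direction errors, occasional no-hits, and
per-phase injection shifts. It does not emulate learning dynamics across
training days, within-session drift, satiety, eye/hand kinematics between
touches, or reward-driven motivation. Trials are conditionally independent
given the scheduler state, so real-data features like slow autocorrelation
in lapse rate are absent: passing recovery tests shows the pipeline is
correct and well-calibrated under the stated generative assumptions, not
that those assumptions exhaust real behavior.

## Problem sizes and tolerances

Unit and property tests run on sessions of 150–4000 trials. The
acceptance-level tests use: 1,000 random 2×2 tables against the closed-form
χ² oracle at 1e−9; 1,000 random p-vectors against a brute-force Holm
enumeration; 100 random-parameter sessions for the count identities; 500
null (saline) session pairs of 1800 trials for type-I calibration (0.05 ±
0.02 pooled over the six sequence movements, whose per-phase counts ≈ 150
keep the χ² approximation honest) and Holm family-wise control (≥ 93%
clean pairs); and 200 anisomycin-preset pairs of 1200 trials for blind
recovery (χ² rejection at p < 0.001 in > 99% of replicates on the showcase
movements, no Random-task movement Holm-significant in ≥ 90%, pooled rates
within 3 binomial SEs of generative truth). The acceptance script uses six
sessions of 3000 trials per phase. These sizes are the package's chosen
defaults for statistically decisive yet quick checks; all Monte-Carlo tests
are seeded and deterministic.

## Known limitations

* The trial-log adapter for deposited spreadsheet data requires a
  user-supplied column mapping; no deposited schema is hard-coded.
* Sessions simulated under one preset are exchangeable, so cross-session
  variance (and hence population paired-test p-values) is smaller than in
  real data where effect topography varies by session; population-level
  outputs should be read structurally, not as forecasts of specific
  p-values.
* A rare trial that follows a no-hit in the Repeating task derives an
  inflated RT (the inter-touch interval spans the missed response window);
  this is faithful to the stated RT definition, and such trials are almost
  always excluded as corrective or are error repeats.
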