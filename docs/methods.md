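# Methods

## Problem setting

Wrist-worn actigraphy devices accumulate movement into per-minute
*activity counts*. A day of counts, summarized as 24 hourly means, is a
surprisingly stable behavioural signature: a classifier trained on such
daily profiles can identify which user produced a given day. `actispoof`
studies the privacy exposure of such identification models in a
*black-box* setting: an attacker who can only query the model and
observe its confidence scores can synthesize a profile the model accepts
as a chosen target user — an *impersonator example* — and that profile
leaks sensitive structure (when the target wakes and sleeps).

Formally, with a fitted model exposing a confidence score
`f(x, t) ∈ [0, 1]` that profile `x` belongs to user `t`, the attack
searches for

    x* = argmax_{x ∈ [0,1]^d} f(x, t),    d = 24.

No gradients, parameters or architecture are available; only the scalar
score per query.

## Feature extraction

Per user, each calendar day becomes a vector `h1..h24` of mean activity
counts per hour (`h1` covers 00:00–00:59). Hours with no recorded
minutes get the sentinel −1; the hourly mean divides by the number of
recorded minutes in the bin, not a fixed 60 (gaps are device-off
periods, not zeros). The first calendar day of every recording is
dropped unconditionally — recordings typically start mid-day and would
contribute profiles that are mostly sentinels. Features are then min–max
normalized per feature over the whole supplied corpus, after sentinel
assignment, so −1 participates as an ordinary value; a degenerate
feature (max = min) maps to 0. Normalization statistics are retained so
new raw profiles can be projected through a training corpus's scaling
(with clipping to [0, 1]); whether to fit statistics corpus-wide or
train-only is a caller choice — corpus-wide is the default.

## Identification model and oracle

The target model is a 500-tree random forest over the 24 features,
predicting the user id. Identification quality is evaluated by repeated
per-user 50/50 splits (10 iterations): each user's rows are split
independently, so both halves cover every user. TPR and TNR are
one-vs-rest per user and macro-averaged — the conventional way to report
single sensitivity/specificity numbers for a multiclass identification
task; balanced accuracy is their mean.

The `Oracle` wrapper exposes only `query(x, t)` (the model's probability
for class `t`; in `binary` mode, 1 iff the top prediction equals `t`)
and `label_query(x)`, and counts every evaluated row — the attacker's
query budget. Top-class ties are broken toward the lexicographically
smallest user id (classifier classes are kept sorted), so label queries
are deterministic.

Transfer models (naive Bayes, kNN at k = 1/3/5, RBF-SVM, a one-hidden-
layer 64-unit MLP, LDA) use scikit-learn's standard probability route
per family: vote fractions for kNN and forests, Platt scaling for the
SVM, softmax for the MLP, posterior probabilities for NB/LDA. Their
remaining hyperparameters are fixed library defaults, recorded in
`ModelSpec.build`.

## The genetic attack

A real-coded GA over `[0,1]^24` with the queried confidence as fitness:

- **Initialization** — population of `n` genomes, genes i.i.d. U(0, 1).
- **Selection** — linear-rank: selection probability `2r/(n(n+1))` with
  rank `r` (1 = worst), tied fitnesses sharing their average rank (so an
  all-equal population is sampled uniformly).
- **Crossover** (prob. 0.8) — per-gene convex blend
  `child = αa + (1−α)b`, `α ~ U(0,1)` per gene; children therefore stay
  inside the box spanned by their parents.
- **Mutation** (prob. 0.1 per individual) — one uniformly chosen gene is
  resampled from U(0, 1). A per-gene rate mode exists behind a flag.
- **Elitism** — the top `max(1, round(0.05 n))` individuals (half-up
  rounding) are copied unchanged, so the best fitness is non-decreasing.
- **Stopping** — at 1500 generations (2000 for the escalated preset), or
  after 100 consecutive generations without strict improvement of the
  all-time best ("patience").

Attack strength is parametrized purely by population size: weak 10,
medium 20, strong 50, escalated 100. Elites are re-evaluated every
generation, so the query budget is exactly
`population_size × generations_run`. The best fitness is initialized to
0 (the score's lower bound) before the first generation, which makes a
run that never rises above 0 — e.g. against a flat binary oracle — stop
after exactly `patience` generations.

The selection/crossover/mutation operators are standard real-coded
defaults and are deliberately plug-replaceable: `run_attack` only
consumes the breeding step, so alternative operators can be swapped
without touching the loop.

`attack_all_users` runs one independent attack per target (child seeds
fanned out from a master seed via `numpy.random.SeedSequence`) and steps
all runs in lockstep, stacking the active populations into a single
`predict_proba` call per generation. Each run draws from its own
generator, so the results are bit-identical to sequential `run_attack`
calls (asserted in the tests); the batching only amortizes the model's
per-call overhead, which for a 500-tree forest dominates the per-row
cost.

## Success criterion and evaluation

An impersonator example succeeds if the model's top prediction is the
target *and* the confidence is ≥ 0.20 — far above the random-guess
level (1/55 ≈ 0.018 at the original cohort size; 1/20 = 0.05 at the
default synthetic size). Success rates are reported as percentages
rounded half-up to one decimal (so 52/55 → 94.5 and 1/55 → 1.8).

Transferability replays the successful examples against each transfer
family trained on the same training split, judged twice: with the full
criterion and with the threshold dropped (top-1 only). The thresholded
rate can never exceed the unthresholded one; this nesting is asserted on
every report.

The confidence-omission countermeasure reruns the attack against the
binary-mode oracle: fitness is 0/1, so the GA receives almost no
gradient signal and its "best" genome is typically the first random
point the model happened to classify as the target. Final success is
still judged on the underlying model's true confidence with the full
criterion — the defender only changes what the attacker sees, not what
success means. With patience enabled such runs stop roughly 100
generations after their last (often only) improvement; a
`--no-patience` flag forces them to the generation cap, and the report
records which mode was used.

Profile comparisons report Pearson correlation and RMS difference
between the impersonator example and the target's ground-truth profile
(the mean of their training rows); `estimate_active_period` reads
wake/sleep hours off a profile as the endpoints of the longest circular
above-threshold run, demonstrating the sensitive-information leak.

## Synthetic cohort

Real cohorts cannot ship with the package, so a simulator generates
recordings with the structure the attack needs: per-user circadian
identity. The mean count at clock hour `h` is

    λ(h) = night_mean + (day_mean − night_mean) · s(h)

with `s` a product of two logistic ramps rising at `wake_hour` and
falling at `sleep_hour` (scale `transition_width` hours), evaluated on
the circle by taking the maximum over ±24 h shifted copies — so sleep
times past midnight work. Counts are negative-binomial with variance
`dispersion · λ` (`dispersion = 1` is Poisson), and a fraction of
minutes is deleted uniformly at random.

Defaults (20 users × 15 days): wake U(5.5, 9) h, sleep U(21, 24.5 mod
24) h, night U(1, 8) counts/min, day U(120, 400) counts/min, ramp width
U(0.5, 2) h, dispersion U(2, 6), 2% missing minutes. These are typical
wrist-count magnitudes and adult sleep schedules, and make users
identifiable from hourly means, which is the property the attack
presupposes. What the simulator does *not* model: weekday/weekend
structure, naps and fragmented sleep, depression-related activity
differences, device calibration drift, or correlated (whole-evening)
missingness. Consequently the synthetic identification problem is easier
than the real one (the forest is near-perfect here, versus 0.63 accuracy
on real 55-user data), and synthetic success rates are upper-ish bounds:
passing tests demonstrate the attack mechanics and the countermeasure
collapse, not real-world attack rates.

## Problem sizes and numerical choices

The shipped experiments use a 20-user × 15-day cohort for the main
campaign and five 10-user × 10-day cohorts for the strength-ordering
study; these sizes keep a full campaign under a minute while leaving the
identification problem non-trivial (20-way). Other choices of note:

- Improvement for the patience rule means *strict* increase of the
  all-time best fitness, with no tolerance.
- Degenerate min–max features map to 0; constant profiles yield NaN
  correlations rather than errors.
- All randomness flows from explicit seeds through
  `numpy.random.Generator`; per-user and per-stage streams are derived
  with `SeedSequence` spawn keys, so any stage can be rerun in
  isolation.
- Wall-clock timings are not part of any report or assertion
  (hardware-dependent).

## Known limitations

- GA operator details (selection scheme, blend crossover, mutation-rate
  semantics) follow common real-coded defaults; other choices would give
  quantitatively different query counts.
- The binary-mode countermeasure result depends on cohort size: with few
  users, a random point's top-1 confidence clears 0.20 more easily, so
  the collapse is to the 1/n_users guess level, not to zero.
- `estimate_active_period` assumes one dominant active block per day; it
  is not a sleep-scoring algorithm.
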