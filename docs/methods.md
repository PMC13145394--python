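# Methods

This note documents the models, the synthetic-data assumptions, and the
numerical and design choices behind `affectsense`.

## Outcome and blocks

Momentary negative affect (NA) is the arithmetic mean of eight Likert items
(downcast, sad, anxious, nervous, irritable, angry, ashamed, dissatisfied
with oneself), each on 1–7. The achievable scores therefore live on the
1/8 grid in [1, 7]. A beep missing any item is treated as unanswered; there
is no partial scoring.

All sensor features for a beep at time *t* are aggregated over the
half-open window [*t* − 2 h, *t*). Half-openness, anchored at the beep,
prevents double counting across adjacent beeps.

## Feature extraction

**Heart rate** (30-s means every 10 min) is cleaned to the physiological
range [30, 220] bpm, bounds inclusive. Block features: mean, min, max,
population-formula SD (a single sample gives SD 0), and zone minutes with
resting ≤ 60 < moderate < 100 ≤ vigorous bpm. Because the stream is a
fixed 10-minute grid, zone "time" is computed as
`block_length × (samples in zone / samples in window)`; this makes zone
minutes sum exactly to the block length whenever any sample exists. The
alternative (10 min per sample, capped) breaks that conservation at stream
edges and was rejected.

**Steps and activity events** carry start/end timestamps. Cleaning drops
non-numeric or negative counts, non-positive durations, and cadences above
200 steps/min. An event contributes
`value × |event ∩ window| / |event|` to each window — a partition of unity,
so any set of blocks covering all events conserves the raw totals
(validated to 1e-9 relative error).

**GPS** traces are event-based: points appear only when the phone detects a
location change, so traces are sparse, uneven, and often silent for hours
at a stay. Consecutive-point distances use the haversine formula with
R = 6 371 000 m; speeds are distance/Δt; a point is *stationary* iff speed
< 1.4 m/s (walking speed, strict) **and** distance < 150 m. Stationary
points are clustered with DBSCAN using great-circle distance in radians
(ε = 100/6 371 000, i.e. ~100 m) and `min_samples = max(2, ⌈0.03 · n⌉)`
where *n* is the person's total point count; the floor of 2 exists because
DBSCAN degenerates below it. Because library DBSCAN assigns border points
in input order, border points are re-assigned deterministically to the
cluster of their earliest-timestamp core neighbor within ε, and clusters
are renumbered by earliest core timestamp — the partition is then invariant
to input permutation (checked against an independent O(n²) implementation).

*Dwell* — the minutes attributed to a point — is the time to the next
point, capped at 30 min. Without the cap a single check-in could claim a
whole silent night. The cap is a declared parameter, not recovered intent.

*Home detection*: a night is the local 20:00–06:00 window (fixed UTC+1
offset; DST is out of scope). A night counts toward the cluster holding the
maximal dwell in that window; home requires ≥ 4 nights and ≥ 50 % of
assessed nights. If nothing qualifies (common under event-based sampling),
the fallback home is the cluster with the greatest total dwell minutes
(ties: more member points, then lower id). "Most visited" by dwell rather
than raw point count avoids sampling-rate artifacts.

Per-block mobility features: summed consecutive in-window distances (the
segment crossing the window boundary is excluded), in-window point count,
and dwell sums for stationary / transition / home-cluster points.

**Context**: assessment hour, time-of-day bins (early morning 05–09,
morning 09–12, afternoon 12–18, evening 18–23, night 23–05 — the bin edges
are a design choice), weekday, weekend, meteorological season, month, and a
single-site daily weather table (apparent temperature, sunshine hours,
precipitation hours) joined on the local calendar date.

**Person-stable**: age, employability, smartphone type, somatic problems,
psychotropic medication, prior treatment (none/outpatient/inpatient).
28 time-varying features; 6 person-stable features in the `with_PS`
variant.

## Missingness policy and inclusion

Two disjoint mechanisms:

* **Structural absence** — no event happened. Fills: 0 for distance, GPS
  points, transition minutes, steps, all activity minutes; 120 (the full
  block) for minutes at home and minutes stationary.
* **MCAR** — the signal should exist but the sensor failed. Detected when
  heart rate, steps and activity are *all* absent (watch off → all wearable
  cells marked), when heart rate alone is absent while another wearable
  stream proves the watch was worn (HR cells marked), and when GPS is
  absent although the person reported travelling in the last 2 h (all five
  GPS cells marked). Marked cells are imputed in-fold by k-NN. The
  travelling flag is used only for this check, never as a model feature,
  preserving the passive-predictors-only design.

Participants are excluded, in order: (1) fewer than 7 calendar days with
≥ 4 answered beeps; (2) fewer than 50 GPS points in total; (3)
travelling-while-GPS-missing in more than 50 % of available blocks;
(4) after dropping rows whose passive features are all missing, rule 1 is
re-checked. The exclusion log reconciles exactly with the input count.

## Models

All models implement `fit(X, y, groups)` / `predict(X, groups)`;
predictions for participants unseen at fit time are always defined.
Predictions are not clipped to [1, 7]: the intercept benchmarks cannot
leave the scale, and clipping would silently change MAE comparisons.

* **Global / per-person intercepts** — the benchmarks. The per-person
  model falls back to the grand mean for unseen ids and can be *adapted*
  for new users by recomputing means on their adaptation slice.
* **LR, RF, FFNN** (± person-stable features) — standard scikit-learn
  estimators behind a thin group-agnostic wrapper.
* **MERF** — `y_it = f(x_it) + b_i + ε_it`. EM-style alternation:
  (a) fit a random forest on `y − b̂[group]`; (b) from residuals
  `r = y − f̂(X)` (out-of-bag predictions on training rows, falling back to
  in-sample for tiny forests, with the choice recorded in `oob_used_`),
  update `b̂_i = r̄_i · σ_b²/(σ_b² + σ²/n_i)` (BLUP shrinkage); (c) update
  σ² and σ_b² by the Gaussian EM M-step including the posterior-variance
  terms — the moment-matched update with the shrinkage correction, chosen
  over full REML for stability at desk-scale sizes. Convergence is declared
  when the penalized Gaussian objective (recorded in `trace_`) changes by
  less than `tol` relatively; non-convergence returns the last iterate with
  a warning. Setting `fix_sigma2_b=0` provably collapses the model onto the
  plain forest. Cold start: `b = 0`.
* **FFNN + Embedding** — a numpy feed-forward net (ReLU hidden layers,
  linear output, squared error, Adam with global gradient-norm clipping at
  5.0, mini-batches of 64) whose input is the concatenation of a
  d-dimensional per-participant embedding (d = 32 by default; 64 available)
  and the block features. The target is centered internally and the offset
  restored at prediction, which stabilizes early training. Defaults —
  300 epochs, learning rate 5e-3, weight decay 3e-3 on dense weights — were
  chosen for stable convergence across random seeds; the weight decay also
  damps spurious weights on features that can extrapolate far outside the
  training min–max range at transform time (see below). New users are
  served by the mean of the learned embedding rows; `finetune_embeddings`
  creates fresh rows at that mean and optimizes *only* those rows on the
  adaptation data — a SHA-256 hash over the dense parameters verifies the
  freeze contract bit-for-bit.

MERF is deliberately not adapted for holdout users: adapting it would
require refitting the forest, which is inconsistent with the
embedding-only fine-tuning scheme.

## Evaluation design

* **User split**: ~10 % of participants held out, sampled within quartile
  strata of per-person row count (largest-remainder allocation across
  strata), deterministic per seed.
* **Time split**: within every participant, the chronologically first 80 %
  of rows train (floor on fractional counts), the rest test.
* **Tuning**: grouped expanding-window CV — five chronological chunks per
  participant; fold *i* trains on all earlier chunks and validates on
  chunk *i*; the first fold is skipped (its training set would be empty),
  leaving exactly four folds. The preprocessor is refitted inside each
  fold. Ties in mean validation MAE go to the configuration with fewer
  parameters, then to grid order. Small default grids are documented in
  `evaluation.DEFAULT_GRIDS`; the scenario runner skips tuning unless
  grids are supplied, keeping the default end-to-end run desk-scale.
* **Preprocessing** (all statistics from training rows only): k-NN
  imputation of MCAR cells (k = 5), one-hot encoding with the train
  vocabulary (unknown levels map to all-zeros), log1p of non-negative
  numeric columns with train skewness > 1, min–max scaling with train
  bounds — out-of-range values at transform time extrapolate linearly
  rather than clip, which is faithful to the scaling definition but means
  downstream models must tolerate occasional >1 inputs — and removal of
  near-zero-variance columns.
* **Metrics**: MAE, RMSE, and R² with the evaluated split's own label mean
  as baseline (so a global-intercept model scores ≈ 0 and models can go
  negative); a `train_mean` baseline is available as a config switch.
* **Scenarios**: *known users* — train on known users' first 80 %, test on
  their last 20 %; *new users* — predict holdout users' last 20 % without
  adaptation, except the per-person intercept and the embedding net, which
  first adapt on the holdout users' first 80 % (the net via embedding-only
  fine-tuning).

## Synthetic cohort

The generator emulates the study conditions: 8 beeps/day at ~2-h intervals
with ±0.5 h jitter over 14 days. Labels follow

    NA_it = grid( μ + b_i + Σ_f β_f · z_f(window) + circadian(t) + ε_it )

with `b_i ~ N(0, σ_b²)`, AR(1) residuals with stationary SD σ_ε (ρ = 0.3
by default — real within-person autocorrelation is unreported, so ρ is a
free knob, not a calibrated quantity), `z_f` the cohort-standardized true
window feature, and `grid(·)` the projection onto the 1/8 item grid
(latent item values rounded then averaged — this reproduces the
discreteness and, through floor-clipping at 1, the mild right skew of real
EMA scores). Defaults μ = 2.87, σ_b = 0.95, σ_ε = 0.64 were calibrated by
Monte Carlo so the *observed* clipped scores have mean ≈ 2.89 and
SD ≈ 1.09. The default coupling is weak
(β = −0.10 steps, +0.10 minutes-home, +0.10 HR mean), mirroring a regime
where most predictable variance is between persons; tests of the
signal-rich regime raise β explicitly. The circadian amplitude defaults to
0 (time-of-day relevance is documented in the field, but no functional
form is established).

Participants get one home plus three away anchors; excursions follow
straight-line paths at walking (1.25–2.4 m/s) or transport (3–8 m/s)
speeds; GPS points appear every ~45 s while moving, every 20–60 min at
stays, and every ~45 min at home during nights, with ~8 m jitter. Heart
rate sits on a 10-min grid around a personal baseline (lower at night,
elevated while moving); walking legs emit step events at ~105 steps/min;
activity events cover walking, cycling, nightly sleep, and evening rest.
Missingness is injected per block: skipped beeps (default 0.2, matching
~85 answered of 112), watch-off sessions (0.035, matching ~3.4 % HR
missingness), and GPS dropouts (0.08). Ground truth — intercepts, β,
latent labels, true features — survives injection, enabling parameter
recovery.

What the generator does **not** emulate: realistic sleep architecture,
proprietary wearable event detection, running/“active” event types (their
features become structural zeros), correlated missingness (e.g. watch-off
clustering into multi-day gaps), and map-constrained movement. Passing
tests therefore show algorithmic correctness and sane statistical behavior
under the stated generative model, not clinical performance.

## Problem sizes and determinism

All randomness flows through explicit integer seeds into numpy's PCG64
generator; a fixed seed reproduces cohorts, splits, forests and networks
bit-for-bit. The shipped experiments use desk-scale sizes chosen as the
package's defaults: 25–30 participants for end-to-end runs, 60 × 80 for
MERF parameter recovery, 200 participants for label-moment checks.

## Known limitations

* The MERF objective can tick upward slightly between iterations because
  the forest refit is not a monotone EM step; the trace is exposed so this
  is auditable.
* Min–max extrapolation can hand neural models inputs far outside [0, 1]
  when a feature's test-period range exceeds its training range (weather is
  the usual culprit under chronological splits); regularization mitigates
  but does not remove this.
* With few holdout users, new-user R² against the holdout's own mean is
  high-variance and often strongly negative; MAE is the primary metric.
* The night/home rules assume a fixed UTC offset; DST transitions and
  travel across time zones are not modeled.
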