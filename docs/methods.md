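# Methods

This note documents the model, the numerical conventions, the synthetic
benchmark and the design decisions behind `weanest`, in the spirit of a
package methods appendix.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model and preprocessing

Input is long-format increment data: one row per dentine slice with
`sample_id`, `age_at_increment` (years; the median chronological age assigned
to the slice, possibly negative for in-utero formation of deciduous teeth),
`d15N` (‰ vs AIR), `d13C` (‰ vs VPDB) and `tooth_type ∈ {M1, dM1, dM2}`.
Sanity bounds (age in (−1, 25), δ¹⁵N in [−5, 25], δ¹³C in [−35, 0]) are
configurable; out-of-bounds rows are dropped with a logged count, as are rows
missing the age or missing both isotopes.  A row missing a single isotope is
kept with the value as an explicit gap (NaN): gaps are never imputed, and the
feature layer computes each variable's derivatives over its present points
only, zero-filling the missing positions.  Duplicate ages within an
individual are averaged to one row, preserving the one-measurement-per-
timestep assumption of the sequence model.  Individuals with fewer than three
increments are excluded (logged).

δ¹⁵N, δ¹³C and age are z-scored with population (divide-by-n) moments.  The
scaler is fit on the training individuals only and applied to validation and
test data, avoiding leakage; a `--global-scaling` flag fits on the whole
dataset for strict replication of workflows that scaled before splitting.

## Feature engineering

Nine numeric channels per timestep, in fixed order
`[d15N, d13C, age, Δd15N, Δd13C, roll_d15N, roll_d13C, slope_d15N,
slope_d13C]`, computed on the z-scored values (slopes therefore have units of
scaled-‰ per scaled-year).  Edge conventions are explicit so every matrix is
fully finite:

- the first difference is 0 — a leading zero encodes "no prior change"
  rather than a missing flag, so the masked model sees complete numerics;
- the centered 3-point rolling mean shrinks to a 2-point mean at either end,
  preserving length without fabricating values;
- the 3-point local OLS slope (values regressed on age, since the quantity of
  interest is a rate of change over time, not over section index) slides its
  window inward at the edges so a genuine regression is fit at every
  position; series shorter than the window get the single global slope.

All three operators are checked against naive brute-force loops to 1e-10 on
random inputs, plus linearity/shift-invariance property tests.

## Elbow labelling

The supervision target is a regression-free elbow of the δ¹⁵N trajectory,
emulating how practitioners eyeball serial profiles without fitting a curve.
Ages and δ¹⁵N are min-max normalized to [0, 1] (making the detector invariant
to affine rescaling of either axis); the elbow is the sample point with the
maximum perpendicular distance to the chord joining the first and last
points, restricted to points below the chord (the decline side), with ties
broken toward the earliest age.  A total δ¹⁵N range under 0.3 ‰ (configurable)
raises a "no decline" error; if no point lies below the chord (e.g. a convex
rise-then-fall profile) the maximum absolute distance is used with a logged
warning.  δ¹³C is deliberately not used for labelling — it enters the model
only as a feature — because nitrogen is the more robust breastfeeding tracer;
carbon contributes at the representation level, not the target level.

Labels are interpreted as weaning *completion* age in years.  An optional
onset estimate (the age before δ¹⁵N first drops more than the threshold below
its initial value) lets users report an interval.  Elbow ages are
robust-scaled globally — `(x − median) / IQR`, quartiles by linear
interpolation — so the regression target is insensitive to outlying weaning
ages; the median/IQR are persisted with the model and inverted at prediction
time.

## Sequence model

Per-timestep channels are the 9 features plus the 3-channel tooth one-hot
(repeated across timesteps so the recurrent layers see tooth context at every
step).  Sequences are right-padded with zeros to a common maximum length
`t_max` with a boolean validity mask; `t_max` defaults to the training set's
maximum and is persisted with the model, and a longer sequence at prediction
time raises an error with guidance to retrain rather than silently
truncating.  The padding value 0 coincides with the mean of the z-scored
channels, but is irrelevant anyway: masked timesteps carry the recurrent
state through unchanged, which makes predictions *exactly* invariant to the
amount of padding (asserted at 1e-5 in the acceptance suite, and exact in
practice).

Architecture: masking → bidirectional LSTM (`units` per direction, sequences
returned) → dropout → bidirectional LSTM (final state per direction) →
dropout → dense(1, linear).  The LSTM cell uses the standard
input/forget/candidate/output gating with forget bias initialized to 1,
Glorot-uniform weights, and is implemented in NumPy together with full
backpropagation through time; gradients are validated against central finite
differences (rel. tol 1e-4) and the batched forward pass against a naive
per-sample loop.  Dropout is standard (non-recurrent) inverted dropout
between layers; recurrent-state dropout is excluded because Monte Carlo
sampling requires the same stochastic mechanism at train and test time.

Training: Adam at the configured learning rate, MSE loss on the robust-scaled
labels, individual-level batches, ≤ `max_epochs` epochs, early stopping when
validation loss fails to improve for `patience` consecutive epochs
(patience 0 stops at the first non-improving epoch) with best-epoch weights
restored.  Per-epoch train/validation losses are recorded for loss-curve
inspection.  Non-finite loss aborts with a diagnostic.  Splits are at the
individual level: an outer 80/20 train/test split (floor rounding for the
train count), then an inner 80/20 split of the training individuals provides
the early-stopping/grid-search validation set — the held-out test set is
never used to select epochs or hyperparameters.  Everything is seeded;
identical config + seed + data give identical weights and predictions.

Defaults (`ModelConfig()`): 128 units, dropout 0.4, learning rate 0.001,
batch size 8, ≤ 200 epochs, patience 50 — the grid-search optimum of the
compiled-data study this tool operationalizes.  The study's methods text
mentions 0.0005 as a training learning rate while its results report 0.001 as
the selected optimum; the default follows the selected configuration, and
0.0005 remains in the default grid.  Grid search sweeps the full Cartesian
product, trains each candidate identically, and selects the lowest validation
RMSE (validation R² is reported alongside in the results table for audit).

Monte Carlo dropout: 100 stochastic forward passes with dropout active; mean
and sd are computed on the normalized scale and inverse robust-scaled to
years (sd scales by the IQR).  With dropout rate 0 the pass is deterministic
and the sd is exactly 0.  The reported interval, mean ± 1.96 sd, is a normal
approximation offered as a convenience, not a calibrated credible interval.

## Evaluation and method agreement

Metrics are computed in years after inverse robust scaling: RMSE, MAE and
R² = 1 − SSres/SStot about the mean of the reference values (NaN with a
warning when the reference is constant).  Confidence intervals use the
percentile bootstrap — resample prediction/reference pairs with replacement,
1000 iterations, 2.5/97.5 quantiles — chosen as the simplest faithful
bootstrap; it is seeded and errors out if the metric is undefined on more
than 10 % of resamples.  Residuals (reference − predicted) are summarized per
tooth type or per maximum-age quantile bin with median, quartiles, Tukey
whiskers and 1.5·IQR outliers.

The agreement suite consumes a wide table of per-individual estimates from
several methods (it never runs external estimators): Friedman's rank test
with tie correction and the asymptotic χ²(k−1) reference (k = 2 raises,
advising a sign test; fully tied data return χ² = 0, p = 1), pairwise Lin's
concordance correlation with population moments (Lin's original definition;
an n−1 option eases cross-checks against other software), Pearson
correlations, Bland–Altman bias with ±1.96·sd(n−1) limits of agreement, and a
per-individual absolute-difference table for heatmap-style inspection.

## Synthetic benchmark

The simulator is a curve-plus-noise generative model, not a physiological
mixing model: the artifact needs controllable ground truth more than
biogeochemical realism.  Each individual draws a breastmilk fraction S(t)
equal to 1 before onset and 0 after completion, linear in between by default
(a logistic variant matched at the 1 %/99 % points is available); isotope
values are `baseline + enrichment · S(t)` with baselines δ¹⁵N ~ N(9.5, 1.0²)
and δ¹³C ~ N(−19.5, 0.8²), enrichments U(2, 3) and U(0.5, 1.2) ‰, onset
U(0.3, 1.5) y, duration U(0.5, 2.5) y, and i.i.d. Gaussian measurement noise
(default sd 0.15 ‰ per isotope).

Increment ages emulate serial sectioning at the sub-annual (≤ 6 months)
resolution characteristic of incremental dentine: consecutive increments are
0.25–0.75 y apart, the first sits just inside the tooth's formation window
(M1 0.3–9.0 y; dM1 −0.3–2.5 y; dM2 0.0–3.5 y — deciduous profiles may begin
before birth, and all stages tolerate negative ages), and profiles that
overrun the window are compressed onto it.  Onset/duration draws are
truncated so completion precedes the penultimate increment by a small margin:
a profile whose post-weaning plateau is not recorded by at least its final
two increments carries no completion signal, mirroring the fact that
compiled training datasets consist of individuals whose elbow was
identifiable in the first place.  Counts per tooth type follow a 227:23:29
M1:dM1:dM2 mix by largest-remainder apportionment, the composition of the
compiled dataset the benchmark emulates.  A fixed seed yields byte-identical
CSVs.

What the simulator does *not* emulate — and what passing tests therefore do
not show about real data: physiological stress effects on δ¹⁵N, diagenesis,
inter-population differences in dentine apposition, correlated measurement
error, and heterogeneous sectioning/age-assignment protocols.  The benchmark
demonstrates that the pipeline recovers known schedules under its own
generative assumptions; accuracy on archaeological material must be judged
against the published real-data evaluation workflow, which this package
reproduces given the compiled increment table.

Benchmark problem sizes were chosen to exercise the full default
configuration while keeping runs laptop-friendly: 500 individuals for the
elbow-recovery rates and 400 individuals (80 held out) for the end-to-end
training benchmark, which completes in a few minutes on one CPU core.

## Known limitations

- The elbow label discretizes to sampled ages; its error is bounded by the
  local sampling interval, so sparsely sampled profiles carry noisier labels.
- MC-dropout sds are a heuristic uncertainty; they rank individuals sensibly
  (and grow with the dropout rate) but are not calibrated probabilities.
- The model requires ≥ 3 increments and a detectable δ¹⁵N decline; profiles
  that never reach the post-weaning plateau are excluded at labelling time
  rather than extrapolated.
- Time-aware recurrent cells and explicit imputation of irregular sampling
  are out of scope; gaps are masked, not modelled.
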