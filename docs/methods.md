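# Methods

This note records the modelling assumptions, the numerical choices, and the
places where the design was genuinely open, in the order the data flows
through the package.

## Signal model and preprocessing

A recording is a C-channel waveform in microvolts at a single sampling rate
fs.  The only preprocessing applied is filtering and segmentation — no
re-referencing, artifact rejection or resampling (deliberately: the model is
meant to learn from raw waveforms).

* **Filters.** Zero-phase Butterworth of order 4, applied forward-backward
  (`scipy.signal.sosfiltfilt`).  The family and order are a package choice
  (standard EEG practice, and the analytic magnitude response makes the
  filters testable); the effective amplitude response is the squared
  Butterworth magnitude, exposed as `filter_frequency_response` for use as
  an oracle.  Preset bands: 0.1–70 Hz band-pass for scalp diagnosis
  recordings (keeps delta through gamma), 0.5 Hz high-pass for neonatal
  monitoring (drift/DC removal).  Cutoffs at or above Nyquist are rejected.
* **Segmentation.** Consecutive non-overlapping windows of `window_s`
  seconds; `window_s * fs` must be a positive integer; the trailing partial
  window is dropped; a record shorter than one window yields an empty
  EpochSet rather than an error.  Epoch windows never overlap — overlap
  would multiply the epoch count and leak information across splits.
* **Window labelling.** When labels come from annotations, a window is
  positive if annotated intervals cover at least 50 % of it.  The threshold
  is a parameter of `annotation_overlap_labeler`; 50 % is the package
  default because it makes the label the majority state of the window.
* **Splits.** Stratified holdout uses largest-remainder rounding: per-class
  training counts are `floor(frac·n_c)` plus one for the largest fractional
  remainders until the overall total reaches `round(frac·N)`; ties break by
  class index.  This makes a 0.7 split of a 5+5 set give 7/3 with per-class
  counts {4,3}.  Epoch-level splitting is the default (mirroring common
  baseline practice); `kfold(..., grouped=True)` keeps all epochs of a
  subject in one fold and is the leakage-safe option whenever several
  epochs derive from one recording.

## Architecture

* **Channel gate.** `σ(W₁W₀ x_avg + W₁W₀ x_max)` with a shared two-layer
  MLP and no biases; squeeze ratio r defaults to `max(1, C // 2)` because
  datasets in this domain go down to C = 4 channels, where the
  computer-vision convention r = 16 would collapse the bottleneck to zero.
  The gate is applied once, to the raw [T × C] input, before embedding —
  the gate multiplies the input signal, not an internal representation.
* **Embedding.** Conv1d (kernel 3, same padding) from C channels to
  d_model features, plus non-learned sinusoidal position codes.  The
  embedding is a package decision (how C becomes d_model is otherwise
  unconstrained); position codes are toggleable
  (`use_position_encoding`, default on) since nothing in the architecture
  pins them down.
* **Sparse attention.** `u = max(1, ceil(c·ln L))` active queries (capped
  at L), placed at `floor(kL/u)` — deterministic, content-independent, and
  shared across heads; the query factor c (default 1) generalises the
  budget.  Active rows get full softmax attention over every key; lazy rows
  are assigned the exact column mean of V (a literal assignment, not an
  approximation — tests compare it bitwise).  The mean is the full column
  mean of the layer's value matrix; a running mean would make the fill
  depend on query order, which nothing in the formulation suggests.
* **Encoder layer.** Post-norm residual blocks inherited from the vanilla
  transformer: attention → dropout → add & layer-norm → position-wise FFN
  (ReLU, width d_ff) → dropout → add & layer-norm.  Dropout 0.1.
* **Distilling layer.** Conv1d (d_model → d_model, kernel 3, same padding),
  ELU (α = 1), max-pool kernel 3 / stride 2 / padding 1.  The pool geometry
  halves even lengths exactly (`L' = ceil(L/2)`), which is what lets
  T = 2048 exit a five-stage stack at 64.
* **Layer plan.** Sparse layers precede full layers; one distilling stage
  after each of the first `n_pool_layers` attention layers, none after the
  last.  With the default counts (3+3 attention, 5 pool) this is the only
  arrangement consistent with "a distill after each encoder layer" and
  five pools over six layers.  The plan is a pure function of the config
  and can be overridden.
* **Predictor.** Mean over the remaining time positions, then an affine
  map to logits; softmax only inside the loss and the metric computation.
* **Initialisation.** Uniform fan-in scaling (±1/√fan_in) from
  `ModelConfig.seed`; identical config + seed ⇒ bitwise identical
  parameters, which the reproducibility tests rely on.

### Input-length budget

With the default pool geometry the per-layer recursion `ceil(L/2)` never
drops below 1, so the literal length bookkeeping accepts any T.  The
configuration contract is instead the strict-halving budget
`T ≥ 2^n_pool_layers`; shorter inputs raise a configuration error naming
the minimum, and sweep tuples violating it become error rows rather than
crashes.

## Training

Adam (β = 0.9/0.999, ε = 1e-8) on categorical cross-entropy — the loss and
optimiser are package defaults (the field standard for this kind of
classifier), surfaced explicitly in `TrainConfig`.  Per-dataset presets:
mdd/helsinki 50 epochs, batch 64, lr 1e-3; pharmaco 300 epochs, batch 32,
lr 1e-4.  No scheduler and no early stopping; the per-epoch loss history is
kept on the results object.  A non-finite loss aborts with a diagnostic.
Batch order and dropout masks derive from `TrainConfig.seed`, so a fit is
exactly reproducible on one machine.

The network runs on the package's own NumPy reverse-mode autodiff engine
(float32 parameters; conv and pooling built on an im2col `unfold`
primitive; max gradients route to the first argmax; softmax is a fused,
shift-invariant primitive so long-sequence attention stays memory-lean;
cross-entropy is fused with softmax for stability).

## Metrics and protocols

Accuracy, precision, recall, F1 from one-vs-rest confusion counts; binary
problems report the positive class, multiclass problems report macro
averages (unweighted over classes — the conservative choice when class
support is unequal) with per-class values retained.  ROC-AUC uses the
positive-class score for binary and macro one-vs-rest for multiclass; a
single-class label vector makes the curve undefined, reported as missing
with a warning.  Aggregates over folds/repeats are mean ± sample standard
deviation (n−1 denominator).

Protocols: `run_holdout_repeats` (independent stratified 7:3 splits, fresh
model per repeat), `run_cv` (k-fold, optionally grouped; every epoch tested
once), `run_ablation` (the four-row switchboard over channel attention ×
sparse attention × distillation, all rows on the same split and seed so
differences are architectural), `run_sensitivity` (7-tuple grid
[sparse, full, conv, pool, d_ff, d_model, heads], invalid tuples reported
as error rows).

## Synthetic benchmark

The generator emulates the two features of EEG the model is built to
exploit: a 1/f^β Gaussian background (synthesised in the frequency domain
for exact spectral control, standardised to unit variance per channel) and
class-specific band-limited oscillations confined to target channels, with
optional Hann-windowed sinusoid bursts at Poisson onsets as a crude
stand-in for rhythmic ictal activity.  It does **not** model volume
conduction, inter-channel correlation structure, non-stationarity, or real
artifacts — so passing tests demonstrate that the pipeline and model are
wired correctly and can learn spectral-spatial class structure, not that
clinical-grade accuracy transfers to real recordings.

The standard benchmark (`two_class_alpha_task`) is two classes on
4-channel, 128 Hz, 4 s epochs, 200 epochs per class: a weak diffuse theta
class versus an alpha class with gain 3 on channels 0–1, SNR 1, seed 7.
The desk-scale encoder for it is reduced to 2 sparse + 1 full layer,
3 distilling stages, d_model 64 — d_ff 128 and 8 heads keep the full-scale
width ratios — trained for 3 epochs (the loss plateaus near zero by then;
see the worked example).  These sizes keep the full 5-fold
cross-validation and the four-row ablation tractable on a single CPU while
leaving the protocol itself identical to the full-scale one.

## Known limitations

* The engine is CPU NumPy; full-scale configurations (d_model 128,
  T = 2048, tens of training epochs) train slowly compared to GPU
  frameworks.  The architecture and protocols are size-independent.
* EDF support targets the common 16-bit single-rate case; mixed
  per-channel rates are rejected rather than resampled.
* No hyperparameter optimisation beyond the explicit sensitivity grid, and
  no significance testing across models.
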