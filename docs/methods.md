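# Methods

This note documents the models and procedures implemented in `hastf`,
the defaults chosen where the design was genuinely open, and what the
synthetic experiments do and do not demonstrate.

## Signal model and features

Band-limited EEG within each of the five rhythm bands is treated as
Gaussian, so differential entropy per 1-s patch reduces to
`½ ln(2πe σ²)` in nats. σ² is the **population** variance of the patch
samples (treating σ² as the distribution parameter); the unbiased
estimator is available via `de_feature(..., ddof=1)`. Zero-variance
patches raise a degenerate-input error rather than being clamped,
because a silent floor would hide dead channels.

Filtering uses a third-order Butterworth bandpass per band, applied
forward-backward by default (zero phase, effective order six); a causal
mode is available (`FilterBank(zero_phase=False)`). Band edges are
Delta 1–4, Theta 4–8, Alpha 8–13, Beta 13–31, Gamma 31–50 Hz, which
requires `fs ≥ 100 Hz`.

Segmentation is strictly non-overlapping: `floor(usable/T)` windows per
trial, trailing remainders discarded, every window inheriting its trial's
label. The 3-s pre-stimulus baseline of 32-channel-style trials is
dropped by default (`baseline="drop"`); no baseline-difference
subtraction is performed — the option exists as a config knob because
part of the 4D-feature literature subtracts baseline DE, but the default
pipeline does not.

DEAP-style continuous ratings are binarized at 5 with *high iff
rating > 5*, so a rating of exactly 5.0 is labeled low.

## Grid mapping

The shipped `deap32` and `seed62` placement tables put row 0 anterior and
column 0 left, midline on column 4, and pin fringe electrodes (F7/F8,
T7/T8, P7/P8) to the outermost columns of their row. Fringe/cerebellar
placements that are ambiguous in print-resolution topographic diagrams
(CB1/CB2) are noted in the table comments. Unoccupied cells are
zero-filled; no spatial interpolation is performed, so the inverse map is
exact and value-conserving. Custom montages are plain-text
`channel,row,col` files.

## Spatial attention

The energy of position `t` against the other `M−1` positions (targets +1
for `t`, −1 for the rest, L2 penalty λ on the slope) has closed-form
minimum `e* = 4(σₜ²+λ) / ((t−uₜ)²+2σₜ²+2λ)`, with `uₜ`, `σₜ²` the
leave-one-out mean and variance. Notes:

- The leave-one-out statistics are computed exactly from full-map sums
  (`uₜ = (S−t)/(M−1)`, `σₜ² = (S2−t²)/(M−1) − uₜ²`), no per-position
  loops. A `shared` mode (all M positions) is provided as a faster
  approximation.
- The energy-minimizing slope for this target assignment is
  `w = +2(t−u)/((t−u)²+2σ²+2λ)`; the opposite sign — which appears in
  part of the parameter-free-attention literature — corresponds to
  swapping the two targets and leaves the minimum value `e*` unchanged.
  The tests verify `e*` against a Nelder-Mead minimization of the energy
  itself.
- λ defaults to 1e-4 (dimensionless, relative to feature variance); it
  only matters when a map is nearly constant, where `e* → 2` and all
  weights tend to `sigmoid(½) ≈ 0.6225`.
- `M` is the number of positions of the map the attention acts on: all
  81 grid cells for post-convolution feature maps, but only the occupied
  electrode cells for attention computed directly on montage-masked input
  grids (visualization and the convolution-free variant in `viz`), so
  fill values never influence the statistics.
- Attention is applied once, to the final convolution output, before max
  pooling. It has exactly zero trainable parameters and never changes a
  value's sign; gradients flow through both the weights and the values.

## Architecture

UCCF: five stride-1 convolutions, 3×3 kernels with padding 1 for layers
1–4 and a 1×1 kernel with padding 0 for layer 5 (padding 1 on a 1×1
kernel would grow the map), so the 9×9 size is invariant throughout.
Skip wiring: layer 2's output concatenates into layer 4's input and
layer 1's into layer 5's. Reference filter counts are (64, 128, 128,
64, 32); the reference encoder is 6 post-norm layers, 8 heads, model
width d = 256 with QKV width equal to d and FFN hidden width 128 — an
inverted bottleneck, kept as configured because both widths are explicit
settings. Max pooling is 2×2 stride 2 (floor semantics: 9→4); the
classifier head is a single affine map of the class token. Class token
and positional encodings initialize from a standard normal truncated to
[0, 1] (`token_init="normal"` gives plain draws). Dropout defaults to 0.

The network runs on a compact reverse-mode autodiff core written on
numpy, with hand-written vector-Jacobian products for convolution
(offset-sum matmuls — faster than im2col at 9×9), pooling, softmax and
the elementwise ops; every gradient is pinned down by central-difference
checks in `tests/test_autodiff.py`. Training uses cross-entropy with
AdamW (decoupled weight decay); reference settings lr 1e-4, weight decay
1e-4, batch 32, 100 epochs, no early stopping.

## Cross-validation and statistics

Units are shuffled with a seeded generator and partitioned into five
near-equal contiguous folds; every unit tests exactly once. The default
split unit is the **trial**, keeping all windows of a trial in one fold —
window-level splitting is implemented (`split_unit="window"`) but leaks
within-trial correlation into the test folds and typically inflates
accuracy, so it must be requested explicitly. Each fold trains a freshly
initialized network seeded from `(seed, fold_id)`; runs are
bit-reproducible.

Accuracy is `100·(TP+TN)/(TP+FP+TN+FN)`; spread over folds is the
population standard deviation. Ablation variants (`All`, `Wo-Sc`,
`Wo-SA`, `Wo-UCCF`, `Wo-SAFE`, `Wo-TAFE`) are trained on identical folds
(paired design). The replacement heads for the bypassed stages are
minimal by construction — flatten+affine in place of the spatial stage,
mean-over-patches+affine in place of the temporal stage — to isolate each
module's contribution. One-way ANOVA is computed by direct sum-of-squares
decomposition (checked against `scipy.stats.f_oneway`); Games-Howell
pairwise comparisons use per-pair Welch-Satterthwaite degrees of freedom
and the studentized-range distribution at the 95% family level (checked
against `pingouin.pairwise_gameshowell`). Analytic intervals are the
default; `bootstrap_bca=N` adds a seeded bootstrap bias estimate and BCa
interval for comparison with published bias-corrected tables.

## Synthetic data

Each channel is 1/f^a Gaussian noise (spectral shaping in the frequency
domain, unit standard deviation, a = 1 by default) plus one
random-phase sinusoid per band at amplitude 0.3; for target-class trials
the sinusoid amplitude in the effect band on the effect channels is
multiplied by `effect_gain` (default 3). The effect is multiplicative on
narrowband amplitude — mirroring the band-power features the pipeline
consumes — not on broadband noise. Each subject draws from an
independent stream spawned from `(seed, subject_index)`.

What the generator does *not* emulate: ocular/muscular artifacts, volume
conduction and inter-channel correlation, non-stationarity, realistic
label noise, or inter-subject variability of effect topography. Passing
the synthetic experiments therefore demonstrates that the implementation
is correct and can recover a known band-limited class difference; it
says nothing about accuracy on real recordings.

## Problem sizes of the shipped experiments

The desk-scale preset — filter counts (8, 16, 16, 8, 8), d = 32, 2
encoder layers, 4 heads, 20 epochs at lr 1e-3 — is the package's
configuration for single-CPU experimentation; its defaults were fixed
when the preset was written. The end-to-end checks use one synthetic
subject (40 trials of 63 s, 280 windows of 8 patches), a label-shuffled
control of the same size, and ten 10-trial subjects for the
attention-ranking check. The reference-scale configuration (6 layers,
d = 256, 100 epochs) is available via `reference_scale_config()` /
`TrainConfig()` and is what one would run on real, licensed recordings.

## Known limitations

- Subject-dependent evaluation only; no cross-subject transfer.
- No artifact removal or re-referencing: inputs are assumed cleaned.
- The convolution-free attention map on input grids is a linear-algebraic
  readout, not a trained saliency method; with a trained network,
  `stage="features"` averages attention over learned feature maps whose
  cells no longer correspond one-to-one to electrodes.
- Games-Howell p-values rely on the studentized-range tail; for very
  small per-group counts (n < 4) they are approximate.
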