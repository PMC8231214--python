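# Methods

`collarcnn` classifies the behaviour state of a housed steer — rumination,
eating, or other — from the 3-axis acceleration stream of a neck-mounted
collar sampled at 10 Hz, and quantifies what it costs to run that
classifier on a duty-cycled micro-controller. This note records the models
and procedures the package implements, the parameters that matter, the
numerical choices made where the design was open, and what the synthetic
herd does and does not establish.

## Signal model and preprocessing

A collar rotates slowly around the neck, so each axis carries a
time-varying projection of gravity on top of motion-induced acceleration.
The package removes it with a first-order difference per axis,

    Δs[t] = s[t] − s[t−1],   s ∈ {x, y, z},

which annihilates any constant offset exactly and attenuates components
slow relative to the 0.1 s sampling interval. Differencing is applied to
the full trace *before* windowing, so every window has exactly
L = window_seconds × 10 samples; per-window differencing would have made
window geometry depend on the preprocessing order. Labels and timestamps
align to the later sample of each difference pair.

Differenced traces are cut into contiguous, non-overlapping windows (90 s
by default; 60 s and 120 s are supported for the window-length study) and
each window takes the majority label of its samples. Ties break by the
fixed label order RUMINATION > EATING > OTHER — a deterministic,
documented convention; any fixed order would do, and the tie is a
measure-zero event on real data.

Training sets are balanced by seeded random undersampling to the minimum
(animal, class) cell count, so every animal contributes the same number of
windows of every class and no animal or class dominates the gradient. An
animal missing a class entirely cannot be balanced and is reported by
name. Cross-validation folds partition *animal identifiers* (shuffle,
slice into k near-equal contiguous folds), never windows; a leakage guard
in the training entry point refuses any train/validation pair that shares
an animal, since windows of one animal are strongly dependent and
window-level splits would inflate every score.

## Classifier

The network is a 1D CNN in two segments. The feature extractor stacks
convolutional blocks, each `Conv1d → Dropout → BatchNorm → ReLU`; the
reference configuration has three blocks of 64 filters with kernel 16
(stride 2, valid padding) and a final kernel-1 "expansion" block that
widens the feature map from 64 to 512 channels. Adaptive average pooling
collapses the time axis to one value per channel, which makes the model
length-agnostic: one trained network evaluates 60, 90 or 120 s windows.
The head is a single fully connected layer, 512 → 3, followed by softmax.

Trainable parameters of the reference network: 170,563 — conv weights and
biases, two batch-norm parameters per channel (scale and shift; running
statistics are not trainable), and the head. The two reduced networks the
pruning trajectory passes through have 11,923 (16-filter blocks, 128-wide
expansion) and 1,063 (4-filter blocks, 32-wide expansion) parameters under
the same convention.

The engine is implemented in numpy: convolutions are im2col matrix
products (BLAS sgemm), with reverse-mode gradients for every layer,
checked against central finite differences in float64 in the test suite
and against a direct sliding-dot-product oracle for the forward pass.

### Training policy

AdamW (decoupled weight decay λ = 0.01), base learning rate 1e−4, batch
size 256, at most 50 epochs, early stopping when the validation loss fails
to improve by 0.01 for 15 consecutive epochs; the returned weights are
those of the best-validation-loss epoch. The learning rate follows a
one-cycle schedule: linear warm-up to 10× the base rate over the first 30%
of the scheduled steps, then cosine annealing down to base/100. The peak
factor, warm-up fraction and final divisor are package choices (only the
policy family and base rate are fixed by the reference protocol); the
schedule satisfies lr(0) < lr_peak and lr(final) < lr(0) by construction.

The hyper-parameter search grids over total block count {2, 3, 4}
(the kernel-1 expansion block is always retained as the last block, since
the head width depends on it), feature-block kernel size {8, 16, 32} and
dropout probability {0.1, 0.25, 0.5}, each point evaluated by grouped
k-fold cross-validation repeated 5 times with derived sub-seeds; the spec
with the highest mean macro F1 wins. The reference optimum (4 blocks,
kernel 16, dropout 0.25) is the package default.

## Structured pruning

Within a pruning stage the cumulative sparsity at iteration t (one
iteration per epoch, Δt = 1) follows the cubic schedule

    s_t = s_f − s_f (1 − t/(nΔt))³,  t ∈ {0, Δt, …, nΔt},

with s_f = 0.5 and n = 35 by default: s_0 = 0 and s_{nΔt} = s_f exactly,
monotone in between. At each iteration the target removed-filter count per
block is round-half-away-from-zero of s_t × (stage-initial filters),
bounded so at least one filter survives; the deficit relative to filters
already removed is pruned by ascending ℓ1 norm of the filter weights
(biases excluded; ties keep the lower index). Rankings are recomputed
every iteration, since the interleaved training moves the weights.
Sparsity is *relative to the stage-initial count*, so four 50% stages take
64-filter blocks through 32 → 16 → 8 → 4 while the expansion shrinks
512 → 256 → 128 → 64 → 32 and the head input follows; this is the only
reading consistent with the reference parameter trajectory
(170,563 → 44,323 → 11,923 → … → 1,063).

Removal is structural surgery, not masking: the filter's outgoing conv
row, bias, batch-norm parameters and running statistics are deleted along
with the next layer's matching input channels (or head columns after the
expansion block). Surviving weights are copied bit-exactly — nothing is
re-initialised — and the reduced model's parameter count always equals the
spec-level accounting of its reduced architecture (asserted as an oracle
equivalence in the tests). Between pruning iterations, training continues
at a constant 1e−4 (no annealing, so learning stays active); each stage
ends with a fine-tuning phase under the one-cycle policy (15 epochs by
default). Optimiser moments are re-initialised after each surgery, since
their shapes change; with one epoch between removals the re-warm-up cost
is negligible.

Half-precision reduction casts conv and head weights to FP16 storage while
batch-norm parameters stay FP32 for numerical stability; arithmetic is
FP32 in both variants (as it would be via widening loads on a Cortex-M4),
so FP16 is a storage format and memory accounting uses a uniform
2 bytes/parameter.

## Complexity and energy accounting

* Parameters: the convention above; it is exact, not estimated.
* Memory: parameters × bytes-per-precision / 1024, reported in KiB. The
  exact values for the three reference networks are 666.26 / 46.57 / 4.15
  kB (FP32) and half that for FP16; the stage-1 network (44,323
  parameters) is 173 kB FP32 to the nearest integer.
* Operations: multiply-accumulates of one forward pass — per conv block,
  out_length × in_channels × kernel × out_channels with valid padding and
  the configured strides (default 2 for the kernel-16 blocks, 1 for the
  expansion), plus the head product. Batch-norm/ReLU/pooling arithmetic is
  excluded by default and available via a flag. Because stride and padding
  conventions vary across the literature, MACC totals are reported with
  their settings rather than asserted against any external figure; the
  count is bilinear in per-block channel counts, so the unpruned :
  48-pruned ratio lies in [13, 16] under any fixed convention (ours gives
  13.8 at 899 samples).
* Energy: a duty-cycle model of an STM32L476RG-class target — 80 MHz
  clock, ≈9 cycles per FP32 MACC, 10.2 mA active, 1.6 µA in STOP2 sleep,
  one inference per 90 s window, a 2600 mAh cell, 8760 h/year. For the
  48-pruned network (3.9 M MACCs): 35.1 M cycles, 438.75 ms per inference,
  ≈51.3 µA average draw, ≈5.8 years of operation — comfortably above the
  5.7-year feasibility bar. Vendor current figures for this part class are
  microamps; the arithmetic only closes with that reading. Accelerometer
  sampling current is excluded by default (it is a property of the sensing
  front-end, not the classifier) and can be added as a constant.

## Synthetic herd

The generator emulates the statistical structure the method relies on, at
a scale a single CPU can train in minutes:

* **Bout structure.** Behaviour is a semi-Markov chain: bout-level
  transitions are row-stochastic with zero diagonal (default uniform over
  the other two states) and dwell times are shifted exponentials,
  1 min + Exp(mean − 1 min), so the bout mean equals the configured dwell
  mean exactly and the time fraction per state has the closed form
  π_i d_i / Σ π_j d_j (π the embedded chain's stationary distribution) —
  the oracle for the label-fraction tests.
* **Signals.** Rumination is an amplitude-modulated sinusoid at the chew
  frequency (1.2 Hz default) gated off for ~2 s at regurgitation pauses
  spaced uniformly in 40–60 s; eating is a chew-rate oscillation at higher
  amplitude plus ~1 s broadband head-motion bursts; other is a constant
  per-bout posture with sporadic single-sample spikes. Each axis adds an
  independent random-walk offset (collar rotation / gravity leakage) and
  white sensor noise. Rumination and eating amplitudes overlap, so the
  pair is the hard confusion, as it is on real animals.
* **Defaults.** 18 animals × 4 h at 10 Hz, dwell means 10/8/12 min for
  rumination/eating/other. Field bouts are longer (tens of minutes) and
  field traces are two orders of magnitude longer (the reference data
  average ~190 h per animal); the desk-scale dwell/duration pair is chosen
  so that every animal cycles through every state several times, which the
  per-animal class balancing requires, while keeping a full 5-fold
  cross-validation run under ten minutes on one CPU. Per-animal sub-seeds
  are seed + index, so a herd extends without perturbing earlier animals.

What passing on this herd shows: the pipeline (differencing → windowing →
balancing → grouped CV → training → staged pruning → FP16) is internally
correct, leak-free and able to recover a planted, learnable bout
structure, and the first two pruning stages cost ≤ 0.05 macro F1 on it.
What it does not show: field-level accuracy. Real collars add
animal-specific gaits, feed-dependent chew rates, sensor saturation and
label noise from the ground-truth halter, none of which are modelled;
desk-scale scores (~0.95 macro F1) are therefore expected to exceed
field-scale ones (~0.82) and the two are not comparable.

## Problem sizes used by the shipped checks

The acceptance script runs the accounting and the schedule-driven pruning
surgery on live models (seconds). The pipeline tests train the reference
network on the canonical herd with 8-epoch runs (the easy synthetic task
converges well within that) and exercise two pruning stages at n = 6
iterations per stage with 4 fine-tuning epochs; the schedule endpoint
(50% per stage) is unchanged by the reduced iteration count, which only
coarsens the removal granularity.

## Known limitations

* The MACC count is convention-stamped (strides/padding configurable);
  no claim is made that operations figures quoted elsewhere used the same
  convention.
* Reference memory figures carry one decimal with a non-uniform rounding
  direction; the package reports exact values and a 1-dp display.
* The engine is CPU-only and optimises clarity over throughput; it is
  fast enough for the desk-scale studies it exists to support, not for
  field-scale training.
* Bout dwell distributions are shifted-exponential; real bout-length
  distributions are heavier-bodied (log-normal-like). This affects only
  the realism of the time budget, not any invariant the tests rely on.
* The halter ground truth is taken as given; label noise and halter
  decoding are out of scope.
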