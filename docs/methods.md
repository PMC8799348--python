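# Methods

## Problem and model

`emgcaps` classifies hand gestures from 16-channel surface electromyography
(sEMG) sampled at 1000 Hz.  The classification unit is a sliding window of
`w = 300` samples advanced by `tau = 50` samples.  The pipeline has three
stages.

**Feature fusion.**  Per channel, 14 standard time/frequency features are
computed (RMS, MAV, WL, ZC, DASDV, LOG, SSI, TM3–TM5, FR, IEMG, MFMN, MFMD)
and prepended with a constant 1, giving `f ∈ R^15`.  The outer-product map

    F = sigmoid(α β · f fᵀ),    α = β = 0.5

lifts the feature vector to a symmetric 15×15 matrix whose (i, j) entry
encodes the joint magnitude of features i and j; the leading 1 keeps the raw
features in row/column 0.  In parallel the 300-sample window is stacked into
a 15×20 segment matrix, `(n, l) = (15, 20)` being the factor pair of 300
minimizing `|n − l|` (mirror ties broken toward `n ≤ l`).  Both matrices are
Min-Max normalized per channel matrix (a constant matrix maps to zeros).
The 16 electrodes enter as the depth axis of two convolution branches —
256 kernels of 3×8 (stride 2, valid) on the segment stack and 256 kernels of
3×3 (stride 2, valid) on the feature maps — each yielding 7×7×256
(`floor((15−3)/2)+1 = floor((20−8)/2)+1 = 7`); channel concatenation
(7×7×512) and a 1×1 mixing convolution produce the 7×7×256 network input.
ReLU follows every convolution.

**Improved capsule network.**  A multilevel convolution block applies padded
3×3 and 5×5 convolutions (256 kernels each), concatenates both with its
input (7×7×768) and reduces back to 256 channels with a 1×1 bottleneck.
The map is reshaped into 7·7·32 = 1568 primary capsules of dimension 8 and
squashed.  Dynamic routing by agreement (3 iterations) couples them to 5
action capsules of dimension 16: with prediction vectors
`û_{j|i} = W_ij u_i`, logits `b_ij` start at 0 each forward pass and each
iteration computes `c_i· = softmax(b_i·)`, `s_j = Σ_i c_ij û_{j|i}`,
`v_j = squash(s_j)`, then `b_ij += û_{j|i}·v_j` (the update after the final
iteration is skipped as it would be unused).  Gradients flow through all
iterations; couplings are not detached.

**Squash family.**  A squash rescales `s` to length `g(‖s‖)` along the same
direction; supported length laws:

| kind           | g(x)                          |
|----------------|-------------------------------|
| squash         | x²/(1+x²)                     |
| hsquash        | (x/4)²/(1+(x/4)²)             |
| strict_squash  | 0.69·x²·2^(−0.6x−1.115)       |
| squash_4       | x²/(0.5+x²)                   |
| e_squash       | 1 − e^(−x²)                   |

`e_squash` dominates the original squash for every length
(`(1+x²)(1−e^(−x²)) ≥ x²`), which sharpens sensitivity to length changes at
intermediate activations.  The same kind is used for primary-capsule
squashing and inside routing.  `strict_squash` is printed in the literature
without a direction factor; it is implemented as its scalar law times the
unit vector of `s`, the only reading that returns a vector.

**Loss and prediction.**  Per-class margin loss with `m⁺ = 0.9`,
`m⁻ = 0.1`, `λ = 0.5`, summed over the 5 action capsules and averaged over
the batch; prediction is the argmax of capsule lengths (ties to the lowest
index, for determinism).

## Numerical choices

* The whole network runs in float64 on an in-repo reverse-mode autodiff
  engine (`emgcaps.nn`) — tensors, strided-view convolutions, two-operand
  einsum, softmax, Adam.  Float64 keeps finite-difference gradient checks
  at the 1e-3 level trivially satisfiable when gradients are correct.
* Squash directions are computed with the norm evaluated as
  `sqrt(‖s‖² + 1e-24)`, keeping gradients finite at the zero vector while
  mapping the exact zero vector to the exact zero vector.
* Convolution weights use He (variance-scaling) initialization, biases 0;
  routing transforms `W_ij` are drawn N(0, 0.05²).  All initialization is
  seeded.
* Band integrals (FR) sum power over bins whose center lies in
  `[low, high)`; MFMN/MFMD use discrete sums over the one-sided `|FFT|²`.
  MFMD is the first bin where cumulative power reaches half the total.
* Degenerate all-zero spectra define MFMN = MFMD = 0; FR returns NaN with a
  RuntimeWarning rather than dividing by zero.
* LOG is implemented literally as `exp(mean(S))` (default), with the
  conventional log-detector `exp(mean(log|S|))` available as a variant.
* The ZC threshold ε defaults to 0 (band-passed sEMG has negligible DC
  offset) and requires strict sign opposition `S_i·S_{i+1} < 0`.
* FR bands default to [20, 250) vs [250, 500) Hz — a symmetric split of the
  20–500 Hz acquisition pass-band; configurable.
* Min-Max normalization is applied to the raw per-channel matrices before
  the learned front-end: normalizing learnable-convolution outputs would be
  ill-defined at training time.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `w`, `tau` | 300, 50 samples | window length / increment at 1000 Hz |
| `alpha`, `beta` | 0.5 | outer-map conversion parameters |
| `routing_iters` | 3 | dynamic-routing iterations |
| `squash_kind` | `e_squash` | capsule nonlinearity |
| `m_plus, m_minus, lambda` | 0.9, 0.1, 0.5 | margin-loss margins / down-weight |
| `batch_size` | 32 (displacement), 16 (cross-subject) | minibatch size |
| `learning_rate` | 1e-3 | Adam step size |
| `epochs` | 30 | training epochs (no early stopping, for reproducibility) |
| `width_profile` | `full` (256) / `test` (32) | convolution channel width |

The `test` profile shrinks every 256-channel convolution to 32 channels
(196 primary capsules instead of 1568) so a full train/evaluate run takes
about a minute on one CPU; the `full` profile realizes the reference layer
table exactly.  Training epochs and learning rate are package choices — the
protocol this emulates states only the optimizer (Adam) and batch sizes.

## Synthetic data: what it emulates, and what it does not

No public corpus matches the 16-channel armband recordings this pipeline
targets, so `emgcaps.synthgen` generates data with exactly the structure the
method exploits:

* **Gesture structure** — each of the 5 gestures (HC, HO, RF, WE, WF) is a
  per-channel amplitude envelope: a floor of 0.25 plus `separation` times a
  Gaussian bump (σ = 1.5 channels) centered every 16/5 channels on the
  electrode ring, with ≤5 % seeded per-channel jitter.  `separation = 1` by
  default; 0 collapses all gestures.
* **Signal character** — unit-RMS Gaussian noise band-limited to 20–500 Hz
  by spectral masking (exact band control, no filter-design choices),
  scaled per channel by envelope × subject gain, plus `noise_sd = 0.05`
  white measurement noise.
* **Subject variability** — per-channel log-normal gains (σ = 0.2 in log
  space), standing in for electrode/skin impedance differences.
* **Electrode displacement** — re-donning the armband is modeled as a
  circular rotation of the channel ring (default test-time shift: 1
  channel against training at shift 0).

Scenario defaults are 120 training and 40 test windows per class
(600 / 200 windows total), sized to train in minutes on one CPU at the
`test` width profile.

The generator does **not** simulate motor-unit action potentials, muscle
fatigue, window-to-window temporal correlation, non-stationarity within a
gesture hold, or crosstalk between non-adjacent muscles.  Passing the
end-to-end tests therefore shows that the pipeline recovers labels from
band-limited signals whose discriminative structure lives in cross-channel
amplitude patterns under displacement and gain variability — it does not
certify accuracy on real recordings, where class overlap is far larger
(real-data accuracies for this kind of protocol sit in the 80–90 % range,
not at the ceiling the synthetic scenarios reach).

## Known limitations

* Per-channel Min-Max normalization removes absolute amplitude scale; class
  information survives through the saturation pattern of the sigmoid outer
  map.  Discriminating gestures that differ only by a global amplitude
  factor would require a different normalization placement.
* The NumPy engine is single-threaded apart from BLAS and holds the full
  routing tensor `û` in memory; at full widths it is practical for
  inference and small-scale training, not for large datasets.
* Routing logits are re-initialized every forward pass (standard dynamic
  routing); persisted-logit variants are out of scope.
* The cross-subject scenario draws subjects from one log-normal gain law;
  real between-subject variation also changes spectra and envelope shapes.
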