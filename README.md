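# emgcaps

Feature-fusion capsule networks for hand-gesture recognition from
multi-channel surface electromyography (sEMG).

Myoelectric interfaces classify short windows of 16-channel forearm sEMG
into gestures (hand closed/open, radial flexion, wrist extension/flexion).
Plain CNNs on sEMG images discard feature correlations and lose information
through pooling; this package implements a capsule-network pipeline that
addresses both:

1. **Feature fusion** — per channel, 14 time/frequency features
   `f = [1, x₁ … x₁₄]` are lifted to an outer-product map
   `F = σ(αβ·ffᵀ)` (α = β = 0.5) and fused with the window's stacked
   15×20 segment matrix by stride-2 convolutions (3×3 and 3×8, 256 kernels
   each), channel concatenation and a 1×1 mixer, giving a 7×7×256 input.
2. **Improved capsule network** — a multilevel convolution block
   (3×3 ⊕ 5×5 ⊕ identity → 768 channels → 1×1 bottleneck → 256), 1568
   primary capsules (dim 8), and dynamic routing-by-agreement (3
   iterations) to 5 action capsules (dim 16) whose lengths are class
   probabilities, trained with the margin loss
   `Σ_k T_k max(0, m⁺−‖v_k‖)² + λ(1−T_k) max(0, ‖v_k‖−m⁻)²`
   (m⁺ = 0.9, m⁻ = 0.1, λ = 0.5).
3. **e-Squash** — the capsule nonlinearity `v = (1−e^(−‖s‖²)) s/‖s‖`,
   which grows faster than the classic `‖s‖²/(1+‖s‖²)` squash once the
   length leaves the origin; four alternative squash laws are provided for
   ablation.

Because the armband recordings this pipeline targets are not public, the
package ships a first-class synthetic generator (`emgcaps.synthgen`)
emulating gesture-specific channel envelopes, subject gain variability and
electrode displacement (circular channel rotation), so every stage is
testable end to end.  The network runs on an in-repo float64 NumPy autodiff
engine — no GPU or deep-learning framework required.

## Worked example

```python
import emgcaps as e

# the balanced factorization behind the 15x20 segment matrix
print(e.solve_segmentation(300))        # SegmentPlan(n=15, l=20)

# e-Squash at unit length
print(e.squash_length(1.0, "e_squash")) # 0.6321205588285577  (= 1 - 1/e)

# end-to-end: electrode-displacement scenario, reduced "test" widths
report = e.run_experiment(
    scenario="displacement", squash_kind="e_squash",
    train_config=e.TrainConfig(batch_size=32, epochs=30, repeats=1,
                               width_profile="test"),
    seed=1,
)
print(report.overall_mean)              # 100.0
print(report.per_gesture_mean)          # [100. 100. 100. 100. 100.]
print(report.histories[0]["train_loss"][:4])
# [0.2577, 0.0172, 0.0004, 0.0001]
```

The scenario trains on 120 windows per gesture recorded at electrode
shift 0 and tests on 40 windows per gesture at a one-channel rotation of
the 16-electrode ring.  The margin loss falls from 0.26 to ~0 within a few
epochs and the model recovers every test label — the synthetic gestures are
far better separated than real recordings, where this family of methods
lands in the 80–90 % range.  `report.confusion` holds the 5×5 confusion
matrix; `e.ablate_squash(...)` tabulates all five squash variants.

The same pipeline is scriptable from the shell:

```sh
emgcaps simulate --scenario displacement --seed 0 data.npz
emgcaps train --scenario displacement --squash e_squash model.npz
emgcaps evaluate model.npz data.npz
emgcaps ablate-squash --epochs 10 --repeats 2
```

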