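# Methods

## Problem and model

`mrgan` synthesizes MR-like images from CT slices when only a small set
of registered CT/MR pairs exists alongside much larger pools of CT-only
and MR-only slices.  Two fully convolutional translation networks are
trained jointly — `SynMR : CT → MR` and `SynCT : MR → CT` — against two
discriminators (`DisMR`, `DisCT`), with an objective that mixes four
ingredients:

* **Unpaired adversarial terms (least squares).**  For slices drawn
  from the independent pools, each discriminator scores single images
  per patch and is pushed toward 1 on real and 0 on synthesized images;
  the generator is pushed toward scores of 1:
  `L_D = E[(D(real) − 1)²] + E[D(G(x))²]`, `L_G = E[(D(G(x)) − 1)²]`.
* **Paired conditional adversarial terms (log-likelihood).**  For
  registered pairs the discriminators see a channel-concatenated
  (condition, candidate) pair through a separate head and tail and emit
  probabilities; training ascends
  `E[log D(x, y)] + E[log(1 − D(x, G(x)))]` for the discriminator and
  descends `E[log(1 − D(x, G(x)))]` for the generator.
* **Dual cycle consistency.**  L1 round-trip penalties
  `‖SynCT(SynMR(ct)) − ct‖₁` and `‖SynMR(SynCT(mr)) − mr‖₁`, applied in
  both the paired and unpaired regimes (four cycles in total), weighted
  by λ (default 10).
* **Voxel-wise L1.**  `‖mr − SynMR(ct)‖₁` (and symmetrically for
  `SynCT`) on registered pairs only, weighted by γ (default 100).

Total: `L = L_adv,MR + L_adv,CT + λ·L_dual-cyc + γ·L_L1`.

One outer iteration runs an unpaired phase then a paired phase, each
updating the four networks in the fixed order DisMR, SynMR, DisCT,
SynCT with Adam (β₁ = 0.5 — the GAN-stabilizing convention — β₂ =
0.999), batch size 1, alternation block length `niter = 1`.  The
learning rate is α = 2e-4 for the first 1e5 iterations and decays
linearly to exactly zero over the next 2e5.  Dropping the paired phase
yields a CycleGAN-style unpaired baseline; dropping the unpaired phase
yields a pix2pix-style conditional baseline — both are configuration
options of the same trainer, not separate implementations.

## Architectures

The generator is the residual translation network: 7×7 conv (reflection
padded) → two stride-2 3×3 convs → nine residual blocks (default) →
two fractionally strided 3×3 convs (zero-stuffing upsampling; a
nearest-resize-then-conv alternative is available via
`GeneratorSpec(upsample="resize")`) → 7×7 conv → tanh.  Instance
normalization (no affine parameters) + ReLU follow every convolution
except the last.  Fully convolutional: any input size divisible by 4 is
preserved.

The discriminators are dual-regime PatchGANs: a 1-channel head for the
unpaired regime and a 2-channel head for the paired regime feed one
shared stride-2 trunk, which feeds two tails — the unpaired tail ends
in raw scores (least-squares regime), the paired tail in a sigmoid
(log-likelihood regime).  Five catalogued head/shared/tail filter
configurations D1–D5 are provided, plus arbitrary user triples.  All
convolutions are 4×4; trunk convs use stride 2 pad 1 (spatial halving),
head/tail convs use stride 1 with asymmetric (1, 2) zero padding so
they preserve spatial size — with symmetric padding each such conv
loses one pixel and the deepest tail (D3) would collapse to an empty
score map on 64×64 inputs.  Leaky-ReLU slope is 0.2; the first conv of
each head has no normalization and the last conv of each tail has
neither normalization nor activation.

## Numerical engine

No deep-learning framework is used: the networks run on a compact
reverse-mode autodiff over NumPy float64 arrays (`mrgan._autodiff`),
with convolution via im2col/col2im, instance-norm and upsampling
backward passes written explicitly, and Adam implemented directly.
Every operation's vector-Jacobian product is tested against central
finite differences.  All computations are deterministic given the seed;
there is no threading or non-deterministic reduction, so training
trajectories are bit-reproducible and checkpoint-resume is exact (the
checkpoint stores the four networks, four Adam states, data-RNG state
and iteration counter).

Numerical choices: probabilities are clamped to [1e-7, 1 − 1e-7] before
logs; all losses are means over patches/pixels so λ and γ keep the same
meaning at any image size; weight init is N(0, 0.02) with zero biases;
instance-norm ε = 1e-5.

## Preprocessing and augmentation

Raw CT volumes in Hounsfield units are windowed with the brain window
(length 80 HU, center 40 HU, the `[center − L/2, center + L/2]` display
convention) onto [0, 255]; 8-bit quantization is round-half-up and
happens only when files are written.  Network I/O uses the affine map
[0, 255] ↔ [−1, 1].

Training-time augmentation per draw: horizontal flip (p = 0.5), zero
pad to size + margin (286 for 256; margin scales as size·30/256 for
other sizes) with a uniform random crop back, rotation uniform in
[−5°, 5°] (bilinear, zero fill).  The composition order is fixed as
flip → pad → crop → rotate for reproducibility.  Registered pairs share
one parameter draw; unpaired slices draw independently.

## Synthetic phantoms

Each phantom slice is one outer elliptical "skull" ring plus 2–6 random
interior ellipses on a uniform interior, with randomized center, axes
and orientation.  The CT rendering shows a bright skull (220–245) and
low-contrast interior (80–140 around a base of 100); the MR rendering
applies a fixed piecewise-linear intensity transfer to the same
geometry — monotone and contrast-stretching over the soft-tissue band,
inverted over the skull band (bright bone → dark) — so the mapping a
trained network must recover is known exactly.  Paired samples share
one geometry (optionally translated by an integer misalignment to
emulate registration error); every unpaired slice draws a fresh
geometry.  Additive Gaussian noise (default SD 2 gray levels) is
applied after the mapping and clipped to [0, 255].

What the phantoms do **not** emulate: anatomical structure, partial
volume effects, scanner artifacts, nonlinear misregistration, and 3-D
continuity between slices.  Passing tests therefore demonstrate that
the training algorithm recovers a learnable cross-modality intensity
mapping under the paired/unpaired data regime — not clinical-grade MR
synthesis.

## Desk-scale study conditions

CPU-scale runs use 64×64 phantoms, 20 paired + 60/60 unpaired training
slices, 10 held-out pairs, a generator with base width 4 and 2 residual
blocks, a small discriminator triple (8)/(16, 32)/(16, 1) and 200
combined iterations — sizes at which the full alternating loop
converges in about a minute while preserving every structural property
of the full-scale configuration.  Under these conditions combined
paired+unpaired training reaches held-out MAE ≈ 9 versus ≈ 15–20 for
unpaired-only training at the same budget and ≈ 85–115 for the
untrained generator, reproducing the qualitative regime ordering
(combined < unpaired-only) the method is designed around.

## Known limitations

* Global-statistics SSIM (whole-slice means/variances, population
  estimators) is the implemented definition; it differs from the
  sliding-window SSIM most libraries default to, which is available
  only behind `ssim(..., windowed=True)` for comparison.
* MAE is normalized per pixel (the per-slice L1 sum divided by pixel
  count) — the reading consistent with "average distance between each
  pixel" on an 8-bit scale.
* The engine is CPU-only and float64; full-scale (256×256, base width
  64, 3e5 iterations) training is expressible but not practical —
  the configuration defaults document it, the desk-scale conditions
  exercise it.
* PSNR of identical stacks returns +inf, which report averages exclude.
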