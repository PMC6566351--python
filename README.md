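# mrgan

Cross-modality medical image synthesis: estimate MR-like brain slices
from CT slices by training on a **mixture of paired and unpaired data**.

MR imaging offers soft-tissue contrast that CT lacks, but is slow,
expensive and contraindicated for many patients.  Registered CT/MR
pairs from the same patient are scarce; CT-only and MR-only scans are
plentiful.  This package implements a dual cycle-consistent adversarial
framework that uses both: two translation networks `SynMR : CT→MR` and
`SynCT : MR→CT` are trained against two dual-regime PatchGAN
discriminators by alternating

* an **unpaired phase** — least-squares adversarial losses plus L1
  cycle-consistency (`CT→MR→CT ≈ CT`, `MR→CT→MR ≈ MR`) on independent
  slice pools, and
* a **paired phase** — conditional log-likelihood adversarial losses on
  (condition, candidate) pairs plus a voxel-wise L1 term toward the
  registered reference, plus the same cycle terms,

minimizing
`L = L_adv,MR + L_adv,CT + λ·L_dual-cyc + γ·L_L1` with λ = 10, γ = 100.
Skipping one phase recovers the two classical baselines (CycleGAN-style
unpaired-only, pix2pix-style paired-only) from the same trainer.

Because clinical data cannot ship with the package, a synthetic phantom
generator produces two-modality head phantoms with exactly the assumed
statistical structure: shared geometry within a pair, a known
piecewise-linear CT→MR intensity transfer (bright CT skull → dark MR,
low CT soft-tissue contrast → high MR contrast), and fresh geometry for
every unpaired slice — so mapping recovery is verifiable against ground
truth on a desktop CPU.  The networks run on a small built-in
reverse-mode autodiff engine over NumPy (see `docs/methods.md`).

## Worked example

```sh
# 1. a mixed-regime phantom dataset (64x64): 20 pairs + 60/60 unpaired
mrgan phantoms --image-size 64 --n-paired 20 --n-unpaired-ct 60 \
      --n-unpaired-mr 60 --seed 1 --out data/train

# 2. held-out paired test set
mrgan phantoms --image-size 64 --n-paired 10 --n-unpaired-ct 0 \
      --n-unpaired-mr 0 --seed 1001 --out data/test

# 3. alternating paired+unpaired training, desk-scale network (~1 min;
#    omit --disc-variant to use the full-size published D1 discriminator)
mrgan train --data data/train --out run --image-size 64 \
      --total-iters 200 --base-filters 4 --n-residual-blocks 2 \
      --disc-variant desk --seed 1

# 4. synthesize MR from the held-out CT slices and evaluate
mrgan synth --checkpoint run/checkpoint_final.npz \
      --inputs data/test/paired_ct --out run/synth
mrgan eval --reference data/test/paired_mr --synthesized run/synth \
      --out run/eval
```

The eval step prints a per-patient table such as

```
patient      MAE      PSNR     SSIM
 Pat-01 9.417969 21.890443 0.921194
Average 9.417969 21.890443 0.921194
```

MAE is the mean absolute pixel difference in gray levels (lower is
better; an untrained generator scores ≈ 85 here), PSNR is
`10·log10(255²/MSE)` in dB (higher is better), and SSIM is the
whole-slice structural similarity in (−1, 1] (1 means identical).  The
same library calls are available in Python (`mrgan.generate_dataset`,
`mrgan.train`, `mrgan.synthesize`, `mrgan.build_report`).

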