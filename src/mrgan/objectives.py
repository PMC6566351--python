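"""Loss terms of the dual cycle-consistent objective.

The total objective combines four ingredients:

* least-squares adversarial terms for the unpaired regime — the
  discriminator pushes real patch scores toward 1 and synthesized ones
  toward 0, the generator pushes synthesized scores toward 1;
* negative log-likelihood conditional adversarial terms for the paired
  regime, where the discriminator scores (condition, candidate) pairs
  as probabilities;
* an L1 cycle-consistency penalty requiring each round trip
  (CT→MR→CT and MR→CT→MR, in both regimes: four cycles total) to
  reconstruct its input;
* an L1 voxel-wise penalty between a synthesized image and its
  registered reference (paired regime only).

Weights: total = adv_MR + adv_CT + λ·dual_cycle + γ·voxel_L1 with
defaults λ = 10, γ = 100.

Every function accepts either plain ndarrays or autodiff tensors and
returns a scalar :class:`~mrgan._autodiff.Tensor` (float-convertible);
all reductions are means over patches/pixels so the weights keep the
same meaning at any image size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .errors import ConfigurationError, NumericError, ShapeError

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "EPS_PROB",
    "lsgan_d_loss",
    "lsgan_g_loss",
    "nll_paired_d_loss",
    "nll_paired_g_loss",
    "cycle_loss",
    "voxel_l1_loss",
    "total_objective",
]

LAMBDA_DEFAULT = 10.0
GAMMA_DEFAULT = 100.0
EPS_PROB = 1e-7   # probability clamp before logs


@dataclass(frozen=True)
class LossWeights:
    """λ weights the dual cycle-consistency term, γ the voxel-wise L1."""

    lam: float = LAMBDA_DEFAULT
    gamma: float = GAMMA_DEFAULT

    def __post_init__(self):
        if self.lam < 0 or self.gamma < 0:
            raise ConfigurationError("loss weights must be >= 0")


@dataclass(frozen=True)
class LossBreakdown:
    adv_mr: float
    adv_ct: float
    dual_cyc: float
    voxel_l1: float
    total: float


def _check_finite(t: Tensor, what: str) -> Tensor:
    if not np.all(np.isfinite(t.data)):
        raise NumericError(f"non-finite values in {what}")
    return t


def _check_same_shape(a: Tensor, b: Tensor) -> None:
    if a.data.shape != b.data.shape:
        raise ShapeError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")


def lsgan_d_loss(scores_real, scores_fake) -> Tensor:
    """Least-squares discriminator loss:
    mean((real − 1)²) + mean(fake²)."""
    r = _check_finite(ad.as_tensor(scores_real), "scores_real")
    f = _check_finite(ad.as_tensor(scores_fake), "scores_fake")
    return ad.mean(ad.square(r - 1.0)) + ad.mean(ad.square(f))


def lsgan_g_loss(scores_fake) -> Tensor:
    """Least-squares generator loss: mean((fake − 1)²)."""
    f = _check_finite(ad.as_tensor(scores_fake), "scores_fake")
    return ad.mean(ad.square(f - 1.0))


def _safe_log(p: Tensor) -> Tensor:
    return ad.log(ad.clamp(p, EPS_PROB, 1.0 - EPS_PROB))


def nll_paired_d_loss(prob_real_pair, prob_fake_pair) -> Tensor:
    """Conditional log-likelihood the paired discriminator ASCENDS:
    mean(log p_real) + mean(log(1 − p_fake)).

    The trainer performs ascent by descending the negation.
    """
    pr = _check_finite(ad.as_tensor(prob_real_pair), "prob_real_pair")
    pf = _check_finite(ad.as_tensor(prob_fake_pair), "prob_fake_pair")
    return ad.mean(_safe_log(pr)) + ad.mean(_safe_log(1.0 - pf))


def nll_paired_g_loss(prob_fake_pair) -> Tensor:
    """Paired generator term mean(log(1 − p_fake)), descended."""
    pf = _check_finite(ad.as_tensor(prob_fake_pair), "prob_fake_pair")
    return ad.mean(_safe_log(1.0 - pf))


def cycle_loss(original, reconstructed) -> Tensor:
    """Mean absolute difference between an image and its round-trip
    reconstruction.  The full dual cycle loss is the sum of this term
    over the four cycles, assembled by the trainer."""
    a = ad.as_tensor(original)
    b = ad.as_tensor(reconstructed)
    _check_same_shape(a, b)
    return ad.mean(ad.absolute(a - b))


def voxel_l1_loss(reference, synthesized) -> Tensor:
    """Mean absolute difference between a registered reference and a
    synthesized image (same functional form as :func:`cycle_loss`)."""
    return cycle_loss(reference, synthesized)


def total_objective(adv_mr: float, adv_ct: float, dual_cyc: float, voxel: float,
                    w: LossWeights | None = None) -> LossBreakdown:
    """Assemble the λ/γ-weighted total from already-computed components."""
    w = w or LossWeights()
    for name, v in (("adv_mr", adv_mr), ("adv_ct", adv_ct),
                    ("dual_cyc", dual_cyc), ("voxel", voxel)):
        if not np.isfinite(v):
            raise NumericError(f"non-finite loss component {name}")
    total = adv_mr + adv_ct + w.lam * dual_cyc + w.gamma * voxel
    return LossBreakdown(adv_mr=float(adv_mr), adv_ct=float(adv_ct),
                         dual_cyc=float(dual_cyc), voxel_l1=float(voxel),
                         total=float(total))
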