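"""Applying a trained synthesis network to CT inputs.

At inference time only the CT→MR synthesis network is needed: each CT
slice is normalized to the network domain [-1, 1], passed through the
network, and mapped back to 8-bit gray levels.  Cycle reconstruction
additionally runs the synthesized MR back through the MR→CT network and
reports a per-pixel relative difference map against the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CheckpointError, ShapeError
from .model_zoo import Generator, load_checkpoint, restore_network
from .preprocess import from_network_domain, to_network_domain
from .training import config_from_dict

__all__ = [
    "SynthesisResult",
    "load_generators",
    "synthesize",
    "reconstruct_cycle",
    "relative_difference",
]

REL_DIFF_EPS = 1.0   # gray levels; stabilizes division on dark pixels


@dataclass
class SynthesisResult:
    slices: np.ndarray           # (N, H, W) in [0, 255]
    source_manifest: list | None
    checkpoint_id: str


def load_generators(checkpoint_path: str) -> tuple[Generator, Generator]:
    """Rebuild (SynMR, SynCT) from a training checkpoint."""
    arrays, meta = load_checkpoint(checkpoint_path)
    if "config" not in meta:
        raise CheckpointError("checkpoint lacks a training config")
    cfg = config_from_dict(meta["config"])
    rng = np.random.default_rng(0)   # weights are overwritten below
    syn_mr = Generator(cfg.gen_spec, rng)
    syn_ct = Generator(cfg.gen_spec, rng)
    restore_network(syn_mr, arrays, "syn_mr")
    restore_network(syn_ct, arrays, "syn_ct")
    return syn_mr, syn_ct


def _as_stack(ct_inputs) -> np.ndarray:
    stack = np.asarray(ct_inputs, dtype=np.float64)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ShapeError("expected a slice or a (N, H, W) stack")
    if stack.shape[1] % 4 or stack.shape[2] % 4:
        raise ShapeError(
            f"slice size {stack.shape[1]}x{stack.shape[2]} not divisible by 4"
        )
    return stack


def _run_generator(gen: Generator, stack: np.ndarray) -> np.ndarray:
    out = []
    for sl in stack:
        x = to_network_domain(sl)[None, None]
        y = gen.forward(x).data[0, 0]
        out.append(from_network_domain(y))
    return np.stack(out)


def synthesize(checkpoint: str | Generator, ct_inputs,
               source_manifest=None) -> SynthesisResult:
    """Run the CT→MR network on a stack of CT slices.

    ``checkpoint`` is a checkpoint path or an already-loaded generator.
    Deterministic: identical checkpoint and inputs give identical
    outputs.
    """
    if isinstance(checkpoint, Generator):
        gen, ckpt_id = checkpoint, "<in-memory>"
    else:
        gen, _ = load_generators(checkpoint)
        ckpt_id = checkpoint
    stack = _as_stack(ct_inputs)
    return SynthesisResult(slices=_run_generator(gen, stack),
                           source_manifest=source_manifest,
                           checkpoint_id=ckpt_id)


def relative_difference(a: np.ndarray, b: np.ndarray,
                        eps: float = REL_DIFF_EPS) -> np.ndarray:
    """|a - b| / (b + eps), per pixel, on the 8-bit scale."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ShapeError(f"shape mismatch: {a.shape} vs {b.shape}")
    return np.abs(a - b) / (b + eps)


def reconstruct_cycle(checkpoint, ct_inputs):
    """Round trip CT→MR→CT.

    Returns ``(synthesized_mr, reconstructed_ct, rel_diff)`` where
    ``rel_diff`` is the per-pixel relative difference between the
    reconstruction and the input.
    """
    if isinstance(checkpoint, tuple):
        syn_mr, syn_ct = checkpoint
    else:
        syn_mr, syn_ct = load_generators(checkpoint)
    stack = _as_stack(ct_inputs)
    mr = _run_generator(syn_mr, stack)
    rec = _run_generator(syn_ct, mr)
    return mr, rec, relative_difference(rec, stack)
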