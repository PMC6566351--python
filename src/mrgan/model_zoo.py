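"""Synthesis and discriminator network constructors.

Two fully convolutional synthesis networks (``SynMR``: CT→MR and
``SynCT``: MR→CT) share one architecture: a 7×7 convolution, two
stride-2 downsampling convolutions, a stack of residual blocks (nine by
default), two fractionally strided upsampling convolutions and a final
7×7 convolution with tanh output.  Instance normalization + ReLU follow
every convolution except the last.  First/last convolutions use
reflection padding to suppress border artifacts.

The discriminators (``DisMR``, ``DisCT``) are PatchGANs with a twist:
one network serves both data regimes through an extra head and an extra
tail per regime around a shared stride-2 trunk.  The unpaired head takes
a single image and its tail emits raw patch scores (least-squares
objective); the paired head takes a channel-concatenated (condition,
candidate) pair and its tail ends in a sigmoid (log-likelihood
objective).  The five catalogued variants D1–D5 differ only in the
head/shared/tail filter counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Adam, Conv2d, Tensor
from .errors import CheckpointError, ConfigurationError, ShapeError

__all__ = [
    "GeneratorSpec",
    "DiscriminatorVariant",
    "DISCRIMINATOR_VARIANTS",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "patch_score_map",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1
LEAKY_SLOPE = 0.2


@dataclass(frozen=True)
class GeneratorSpec:
    in_channels: int = 1
    out_channels: int = 1
    base_filters: int = 64
    n_residual_blocks: int = 9
    instance_norm: bool = True
    # "transpose": zero-stuffing fractionally strided conv (the default);
    # "resize": nearest-neighbour upsample followed by a stride-1 conv.
    upsample: str = "transpose"

    def __post_init__(self):
        if self.n_residual_blocks < 1:
            raise ConfigurationError("n_residual_blocks must be >= 1")
        if self.upsample not in ("transpose", "resize"):
            raise ConfigurationError(f"unknown upsample mode {self.upsample!r}")


@dataclass(frozen=True)
class DiscriminatorVariant:
    name: str
    head_filters: tuple[int, ...]
    shared_filters: tuple[int, ...]
    tail_filters: tuple[int, ...]

    def __post_init__(self):
        if not (self.head_filters and self.shared_filters and self.tail_filters):
            raise ConfigurationError("head/shared/tail filter lists must be non-empty")


DISCRIMINATOR_VARIANTS: dict[str, DiscriminatorVariant] = {
    "D1": DiscriminatorVariant("D1", (64,), (64, 128, 256, 512), (512, 1)),
    "D2": DiscriminatorVariant("D2", (64, 64), (64, 128, 256, 512), (512, 512, 1)),
    "D3": DiscriminatorVariant("D3", (64, 64), (64, 128, 256, 512), (512, 512, 512, 1)),
    "D4": DiscriminatorVariant("D4", (64,), (128, 256, 512), (512, 1)),
    "D5": DiscriminatorVariant("D5", (64,), (128, 256, 512), (1,)),
}


# a small non-catalogued variant for CPU-scale runs
DESK_VARIANT = DiscriminatorVariant("desk", (8,), (16, 32), (16, 1))


def resolve_variant(variant: str | DiscriminatorVariant) -> DiscriminatorVariant:
    if isinstance(variant, DiscriminatorVariant):
        return variant
    named = {**DISCRIMINATOR_VARIANTS, "desk": DESK_VARIANT}
    try:
        return named[variant]
    except KeyError:
        raise ConfigurationError(
            f"unknown discriminator variant {variant!r}; known: {sorted(named)}"
        ) from None


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

class _ResidualBlock:
    def __init__(self, ch: int, rng: np.random.Generator, use_norm: bool):
        self.conv1 = Conv2d(ch, ch, 3, rng=rng)
        self.conv2 = Conv2d(ch, ch, 3, rng=rng)
        self.use_norm = use_norm

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv1(ad.reflect_pad2d(x, 1))
        if self.use_norm:
            h = ad.instance_norm2d(h)
        h = ad.relu(h)
        h = self.conv2(ad.reflect_pad2d(h, 1))
        if self.use_norm:
            h = ad.instance_norm2d(h)
        return x + h

    def parameters(self):
        return self.conv1.parameters() + self.conv2.parameters()


class Generator:
    """Residual translation network; spatial shape preserving, tanh output."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        b = spec.base_filters
        self.head = Conv2d(spec.in_channels, b, 7, rng=rng)
        self.down1 = Conv2d(b, 2 * b, 3, stride=2, pad=1, rng=rng)
        self.down2 = Conv2d(2 * b, 4 * b, 3, stride=2, pad=1, rng=rng)
        self.blocks = [_ResidualBlock(4 * b, rng, spec.instance_norm)
                       for _ in range(spec.n_residual_blocks)]
        self.up1 = Conv2d(4 * b, 2 * b, 3, pad=1, rng=rng)
        self.up2 = Conv2d(2 * b, b, 3, pad=1, rng=rng)
        self.tail = Conv2d(b, spec.out_channels, 7, rng=rng)

    def _norm_act(self, x: Tensor) -> Tensor:
        if self.spec.instance_norm:
            x = ad.instance_norm2d(x)
        return ad.relu(x)

    def forward(self, x) -> Tensor:
        x = ad.as_tensor(x)
        n, c, h, w = x.data.shape
        if h % 4 or w % 4:
            raise ShapeError(f"generator input size must be divisible by 4, got {h}x{w}")
        y = self._norm_act(self.head(ad.reflect_pad2d(x, 3)))
        y = self._norm_act(self.down1(y))
        y = self._norm_act(self.down2(y))
        for blk in self.blocks:
            y = blk(y)
        if self.spec.upsample == "transpose":
            y = self._norm_act(self.up1(ad.zero_upsample2d(y, 2)))
            y = self._norm_act(self.up2(ad.zero_upsample2d(y, 2)))
        else:
            y = self._norm_act(self.up1(ad.nearest_upsample2d(y, 2)))
            y = self._norm_act(self.up2(ad.nearest_upsample2d(y, 2)))
        return ad.tanh(self.tail(ad.reflect_pad2d(y, 3)))

    __call__ = forward

    def parameters(self) -> list[Tensor]:
        ps = (self.head.parameters() + self.down1.parameters()
              + self.down2.parameters())
        for blk in self.blocks:
            ps += blk.parameters()
        ps += self.up1.parameters() + self.up2.parameters() + self.tail.parameters()
        return ps


# ---------------------------------------------------------------------------
# discriminator
# ---------------------------------------------------------------------------

class Discriminator:
    """Dual-regime PatchGAN: two heads, one shared trunk, two tails.

    Head and tail convolutions are padded 4×4 stride 1 (size-preserving);
    trunk convolutions are 4×4 stride 2 pad 1 (spatial halving), so the
    patch-score map is the input size divided by 2^len(shared).  The
    first convolution of each head skips
    instance normalization, and the last convolution of each tail has no
    normalization or activation; the paired tail is followed by a sigmoid
    at score time.
    """

    def __init__(self, variant: str | DiscriminatorVariant, rng: np.random.Generator):
        variant = resolve_variant(variant)
        self.variant = variant

        def make_stack(in_ch, filters, stride):
            # stride-1 4x4 convs use asymmetric (1, 2) padding so head and
            # tail preserve spatial size; the trunk halves even sizes
            pad = 1 if stride == 2 else (1, 2)
            convs = []
            for f in filters:
                convs.append(Conv2d(in_ch, f, 4, stride=stride, pad=pad, rng=rng))
                in_ch = f
            return convs, in_ch

        self.unpaired_head, head_out = make_stack(1, variant.head_filters, 1)
        self.paired_head, _ = make_stack(2, variant.head_filters, 1)
        self.shared, trunk_out = make_stack(head_out, variant.shared_filters, 2)
        self.unpaired_tail, _ = make_stack(trunk_out, variant.tail_filters, 1)
        self.paired_tail, _ = make_stack(trunk_out, variant.tail_filters, 1)
        if variant.tail_filters[-1] != 1:
            raise ConfigurationError("discriminator tail must end in 1 channel")

    def _run(self, x: Tensor, head, tail, sigmoid_out: bool) -> Tensor:
        first = head[0]
        last = tail[-1]
        y = x
        for conv in head + self.shared + tail:
            y = conv(y)
            if conv is last:
                break
            if conv is not first:
                y = ad.instance_norm2d(y)
            y = ad.leaky_relu(y, LEAKY_SLOPE)
        return ad.sigmoid(y) if sigmoid_out else y

    def forward_unpaired(self, image) -> Tensor:
        """Raw patch scores for a single image (least-squares regime)."""
        x = ad.as_tensor(image)
        if x.data.shape[1] != 1:
            raise ShapeError("unpaired head expects a 1-channel input")
        return self._run(x, self.unpaired_head, self.unpaired_tail, sigmoid_out=False)

    def forward_paired(self, condition, candidate) -> Tensor:
        """Patch probabilities for a (condition, candidate) pair."""
        cond = ad.as_tensor(condition)
        cand = ad.as_tensor(candidate)
        if cond.data.shape != cand.data.shape:
            raise ShapeError("paired head inputs must share one shape")
        x = ad.concat_channels(cond, cand)
        return self._run(x, self.paired_head, self.paired_tail, sigmoid_out=True)

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for stack in (self.unpaired_head, self.paired_head, self.shared,
                      self.unpaired_tail, self.paired_tail):
            for conv in stack:
                ps += conv.parameters()
        return ps

    def shared_parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for conv in self.shared:
            ps += conv.parameters()
        return ps


def build_generator(spec: GeneratorSpec | None = None,
                    rng: np.random.Generator | None = None) -> Generator:
    return Generator(spec or GeneratorSpec(), rng or np.random.default_rng(0))


def build_discriminator(variant: str | DiscriminatorVariant = "D1",
                        rng: np.random.Generator | None = None) -> Discriminator:
    return Discriminator(variant, rng or np.random.default_rng(0))


def patch_score_map(net: Discriminator, image, condition=None) -> np.ndarray:
    """Per-patch score grid as a plain array (no gradient tracking)."""
    if condition is None:
        return net.forward_unpaired(ad.as_tensor(np.asarray(image))).data
    return net.forward_paired(ad.as_tensor(np.asarray(condition)),
                              ad.as_tensor(np.asarray(image))).data


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def _collect_state(nets: dict, optimizers: dict | None) -> dict[str, np.ndarray]:
    arrays: dict[str, np.ndarray] = {}
    for name, net in nets.items():
        for i, p in enumerate(net.parameters()):
            arrays[f"net/{name}/{i}"] = p.data
    if optimizers:
        for name, opt in optimizers.items():
            state = opt.state_dict()
            arrays[f"opt/{name}/t"] = np.asarray(state["t"])
            for i, m in enumerate(state["m"]):
                arrays[f"opt/{name}/m/{i}"] = m
            for i, v in enumerate(state["v"]):
                arrays[f"opt/{name}/v/{i}"] = v
    return arrays


def save_checkpoint(path: str, nets: dict, optimizers: dict | None = None,
                    meta: dict | None = None) -> None:
    """Write all networks (and optionally optimizer state) to one archive.

    The archive is a NumPy ``.npz`` holding every parameter array plus a
    JSON metadata string (format version, iteration counter, config,
    RNG state).
    """
    import json

    arrays = _collect_state(nets, optimizers)
    meta = dict(meta or {})
    meta["format_version"] = CHECKPOINT_FORMAT_VERSION
    meta["networks"] = sorted(nets)
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> tuple[dict[str, np.ndarray], dict]:
    """Read a checkpoint archive; returns ``(arrays, meta)``."""
    import json

    try:
        with np.load(path) as npz:
            arrays = {k: npz[k] for k in npz.files}
    except Exception as exc:
        raise CheckpointError(f"cannot read checkpoint {path!r}: {exc}") from exc
    if "meta_json" not in arrays:
        raise CheckpointError(f"{path!r} is not a recognized checkpoint archive")
    meta = json.loads(bytes(arrays.pop("meta_json")).decode("utf-8"))
    if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
        raise CheckpointError(
            f"unsupported checkpoint format version {meta.get('format_version')!r}"
        )
    return arrays, meta


def restore_network(net, arrays: dict[str, np.ndarray], name: str) -> None:
    params = net.parameters()
    for i, p in enumerate(params):
        key = f"net/{name}/{i}"
        if key not in arrays:
            raise CheckpointError(f"checkpoint missing parameter {key}")
        if arrays[key].shape != p.data.shape:
            raise CheckpointError(
                f"checkpoint parameter {key} has shape {arrays[key].shape}, "
                f"network expects {p.data.shape}"
            )
        p.data = np.asarray(arrays[key], dtype=np.float64).copy()


def restore_optimizer(opt: Adam, arrays: dict[str, np.ndarray], name: str) -> None:
    n = len(opt.params)
    state = {
        "t": int(arrays[f"opt/{name}/t"]),
        "m": [arrays[f"opt/{name}/m/{i}"] for i in range(n)],
        "v": [arrays[f"opt/{name}/v/{i}"] for i in range(n)],
    }
    opt.load_state_dict(state)
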