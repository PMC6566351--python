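"""Alternating paired/unpaired adversarial training.

One outer training iteration runs ``niter`` unpaired-phase steps
followed by ``niter`` paired-phase steps (either phase is skipped when
its data regime is absent or disabled, which yields the two classical
baselines: unpaired-only ≈ cycle-consistency translation, paired-only ≈
conditional adversarial regression with L1).

Each phase step updates the four networks in a fixed order —
DisMR, SynMR, DisCT, SynCT — every update descending its own loss with
Adam (β₁ = 0.5, β₂ = 0.999, batch size 1 by default) at the scheduled
learning rate: constant α = 2e-4 for the first 1e5 iterations, then
linear decay to zero over the next 2e5.  Batches are drawn uniformly
with replacement; paired batches are augmented with one shared
transform draw per pair, unpaired slices independently.

Checkpoints capture the four networks, the four Adam states, the data
RNG state and the iteration counter, so a resumed run reproduces the
uninterrupted loss trajectory bit for bit.
"""

from __future__ import annotations

import csv
import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Tensor
from .errors import ConfigurationError, DataError
from .model_zoo import (
    Discriminator,
    DiscriminatorVariant,
    Generator,
    GeneratorSpec,
    load_checkpoint,
    resolve_variant,
    restore_network,
    restore_optimizer,
    save_checkpoint,
)
from .objectives import (
    LossBreakdown,
    LossWeights,
    cycle_loss,
    lsgan_d_loss,
    lsgan_g_loss,
    nll_paired_d_loss,
    nll_paired_g_loss,
    total_objective,
    voxel_l1_loss,
)
from .phantom_data import PhantomDataset
from .preprocess import apply_augment, sample_augment_params, to_network_domain

__all__ = [
    "TrainConfig",
    "TrainingState",
    "lr_schedule",
    "unpaired_phase_step",
    "paired_phase_step",
    "train",
    "init_state",
    "prepare_unpaired_batch",
    "prepare_paired_batch",
]

LOG_COLUMNS = ["iteration", "phase", "d_mr", "d_ct", "adv_mr", "adv_ct",
               "dual_cyc", "voxel_l1", "total", "lr"]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the alternating training procedure."""

    alpha: float = 2e-4            # initial learning rate
    batch_size: int = 1            # m
    niter: int = 1                 # alternation block length
    warm_iters: int = 100_000
    decay_iters: int = 200_000
    total_iters: int | None = None  # defaults to warm + decay
    weights: LossWeights = field(default_factory=LossWeights)
    gen_spec: GeneratorSpec = field(default_factory=GeneratorSpec)
    disc_variant: str | DiscriminatorVariant = "D1"
    image_size: int = 256
    seed: int = 0
    checkpoint_every: int = 0      # 0: only a final checkpoint
    mode: str = "both"             # both | paired | unpaired
    augment: bool = True

    def __post_init__(self):
        if self.batch_size < 1 or self.niter < 1:
            raise ConfigurationError("batch_size and niter must be >= 1")
        if self.warm_iters < 0 or self.decay_iters < 0:
            raise ConfigurationError("warm_iters and decay_iters must be >= 0")
        if self.mode not in ("both", "paired", "unpaired"):
            raise ConfigurationError(f"unknown training mode {self.mode!r}")
        resolve_variant(self.disc_variant)

    @property
    def budget(self) -> int:
        return self.total_iters if self.total_iters is not None \
            else self.warm_iters + self.decay_iters


@dataclass
class TrainingState:
    iteration: int
    syn_mr: Generator
    syn_ct: Generator
    dis_mr: Discriminator
    dis_ct: Discriminator
    optimizers: dict[str, Adam]
    rng: np.random.Generator

    @property
    def nets(self) -> dict:
        return {"syn_mr": self.syn_mr, "syn_ct": self.syn_ct,
                "dis_mr": self.dis_mr, "dis_ct": self.dis_ct}


def lr_schedule(iteration: int, cfg: TrainConfig) -> float:
    """Constant α during warm-up, then linear decay to exactly zero."""
    end = cfg.warm_iters + cfg.decay_iters
    if not 0 <= iteration <= end:
        raise ConfigurationError(
            f"iteration {iteration} outside schedule range [0, {end}]"
        )
    if iteration < cfg.warm_iters or cfg.decay_iters == 0:
        return cfg.alpha
    return cfg.alpha * (1.0 - (iteration - cfg.warm_iters) / cfg.decay_iters)


# ---------------------------------------------------------------------------
# state construction / checkpointing
# ---------------------------------------------------------------------------

def init_state(cfg: TrainConfig) -> TrainingState:
    """Fresh networks, optimizers and data RNG, all derived from cfg.seed."""
    seq = np.random.SeedSequence(cfg.seed)
    s_mr, s_ct, s_dmr, s_dct, s_data = seq.spawn(5)
    syn_mr = Generator(cfg.gen_spec, np.random.default_rng(s_mr))
    syn_ct = Generator(cfg.gen_spec, np.random.default_rng(s_ct))
    dis_mr = Discriminator(cfg.disc_variant, np.random.default_rng(s_dmr))
    dis_ct = Discriminator(cfg.disc_variant, np.random.default_rng(s_dct))
    optimizers = {
        "syn_mr": Adam(syn_mr.parameters()),
        "syn_ct": Adam(syn_ct.parameters()),
        "dis_mr": Adam(dis_mr.parameters()),
        "dis_ct": Adam(dis_ct.parameters()),
    }
    return TrainingState(iteration=0, syn_mr=syn_mr, syn_ct=syn_ct,
                         dis_mr=dis_mr, dis_ct=dis_ct,
                         optimizers=optimizers,
                         rng=np.random.default_rng(s_data))


def config_to_dict(cfg: TrainConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if isinstance(cfg.disc_variant, DiscriminatorVariant):
        d["disc_variant"] = dataclasses.asdict(cfg.disc_variant)
    return d


def config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    d["weights"] = LossWeights(**d["weights"])
    gs = dict(d["gen_spec"])
    d["gen_spec"] = GeneratorSpec(**gs)
    if isinstance(d["disc_variant"], dict):
        dv = d["disc_variant"]
        d["disc_variant"] = DiscriminatorVariant(
            dv["name"], tuple(dv["head_filters"]), tuple(dv["shared_filters"]),
            tuple(dv["tail_filters"]))
    return TrainConfig(**d)


def save_training_checkpoint(path: str, state: TrainingState,
                             cfg: TrainConfig) -> None:
    meta = {
        "iteration": state.iteration,
        "rng_state": state.rng.bit_generator.state,
        "config": config_to_dict(cfg),
    }
    save_checkpoint(path, state.nets, state.optimizers, meta)


def load_training_checkpoint(path: str) -> tuple[TrainingState, TrainConfig]:
    arrays, meta = load_checkpoint(path)
    cfg = config_from_dict(meta["config"])
    state = init_state(cfg)
    for name, net in state.nets.items():
        restore_network(net, arrays, name)
        restore_optimizer(state.optimizers[name], arrays, name)
    state.iteration = int(meta["iteration"])
    state.rng.bit_generator.state = meta["rng_state"]
    return state, cfg


# ---------------------------------------------------------------------------
# batch preparation
# ---------------------------------------------------------------------------

def _to_nchw(slices: list[np.ndarray]) -> Tensor:
    arr = np.stack([to_network_domain(s) for s in slices])[:, None, :, :]
    return Tensor(arr)


def prepare_unpaired_batch(pool_ct: list, pool_mr: list, cfg: TrainConfig,
                           rng: np.random.Generator) -> tuple[Tensor, Tensor]:
    """Sample m CT and m MR slices with replacement; augment each slice
    with an independent transform draw."""
    if not pool_ct or not pool_mr:
        raise DataError("unpaired phase requires non-empty CT and MR pools")
    cts, mrs = [], []
    for _ in range(cfg.batch_size):
        ct = pool_ct[int(rng.integers(len(pool_ct)))]
        if cfg.augment:
            ct = apply_augment(ct, sample_augment_params(ct.shape[0], rng))
        cts.append(ct)
    for _ in range(cfg.batch_size):
        mr = pool_mr[int(rng.integers(len(pool_mr)))]
        if cfg.augment:
            mr = apply_augment(mr, sample_augment_params(mr.shape[0], rng))
        mrs.append(mr)
    return _to_nchw(cts), _to_nchw(mrs)


def prepare_paired_batch(pairs: list, cfg: TrainConfig,
                         rng: np.random.Generator) -> tuple[Tensor, Tensor]:
    """Sample m registered pairs; each pair shares ONE transform draw so
    augmentation preserves registration."""
    if not pairs:
        raise DataError("paired phase requires a non-empty paired set")
    cts, mrs = [], []
    for _ in range(cfg.batch_size):
        p = pairs[int(rng.integers(len(pairs)))]
        ct, mr = p.ct, p.mr
        if cfg.augment:
            params = sample_augment_params(ct.shape[0], rng)
            ct = apply_augment(ct, params)
            mr = apply_augment(mr, params)
        cts.append(ct)
        mrs.append(mr)
    return _to_nchw(cts), _to_nchw(mrs)


# ---------------------------------------------------------------------------
# phase steps
# ---------------------------------------------------------------------------

def _zero_all_grads(state: TrainingState) -> None:
    for net in state.nets.values():
        for p in net.parameters():
            p.grad = None


def _update(state: TrainingState, name: str, loss: Tensor, lr: float) -> None:
    # freeze every network except the one being updated so backward
    # skips their (unused) weight gradients; tape was built unfrozen
    for other, net in state.nets.items():
        flag = other == name
        for p in net.parameters():
            p.requires_grad = flag
    _zero_all_grads(state)
    loss.backward()
    state.optimizers[name].step(lr)
    for net in state.nets.values():
        for p in net.parameters():
            p.requires_grad = True


def unpaired_phase_step(state: TrainingState, batch_ct: Tensor,
                        batch_mr: Tensor, cfg: TrainConfig,
                        lr: float) -> LossBreakdown:
    """One pass of the unpaired updates (least-squares adversarial +
    cycle consistency), in order DisMR, SynMR, DisCT, SynCT."""
    lam = cfg.weights.lam

    fake_mr = state.syn_mr(batch_ct).detach()
    d_mr = lsgan_d_loss(state.dis_mr.forward_unpaired(batch_mr),
                        state.dis_mr.forward_unpaired(fake_mr))
    _update(state, "dis_mr", d_mr, lr)

    fake_mr = state.syn_mr(batch_ct)
    adv_mr = lsgan_g_loss(state.dis_mr.forward_unpaired(fake_mr))
    cyc_fwd = cycle_loss(batch_ct, state.syn_ct(fake_mr))
    _update(state, "syn_mr", adv_mr + lam * cyc_fwd, lr)

    fake_ct = state.syn_ct(batch_mr).detach()
    d_ct = lsgan_d_loss(state.dis_ct.forward_unpaired(batch_ct),
                        state.dis_ct.forward_unpaired(fake_ct))
    _update(state, "dis_ct", d_ct, lr)

    fake_ct = state.syn_ct(batch_mr)
    adv_ct = lsgan_g_loss(state.dis_ct.forward_unpaired(fake_ct))
    cyc_bwd = cycle_loss(batch_mr, state.syn_mr(fake_ct))
    _update(state, "syn_ct", adv_ct + lam * cyc_bwd, lr)

    breakdown = total_objective(float(adv_mr), float(adv_ct),
                                float(cyc_fwd) + float(cyc_bwd), 0.0,
                                cfg.weights)
    return breakdown, float(d_mr), float(d_ct)


def paired_phase_step(state: TrainingState, batch_ct: Tensor,
                      batch_mr: Tensor, cfg: TrainConfig,
                      lr: float) -> LossBreakdown:
    """One pass of the paired updates: conditional log-likelihood
    adversarial terms plus cycle and voxel-wise L1 losses."""
    lam, gamma = cfg.weights.lam, cfg.weights.gamma

    fake_mr = state.syn_mr(batch_ct).detach()
    d_mr = -1.0 * nll_paired_d_loss(
        state.dis_mr.forward_paired(batch_ct, batch_mr),
        state.dis_mr.forward_paired(batch_ct, fake_mr))
    _update(state, "dis_mr", d_mr, lr)

    fake_mr = state.syn_mr(batch_ct)
    adv_mr = nll_paired_g_loss(state.dis_mr.forward_paired(batch_ct, fake_mr))
    cyc_fwd = cycle_loss(batch_ct, state.syn_ct(fake_mr))
    vox_mr = voxel_l1_loss(batch_mr, fake_mr)
    _update(state, "syn_mr", adv_mr + lam * cyc_fwd + gamma * vox_mr, lr)

    fake_ct = state.syn_ct(batch_mr).detach()
    d_ct = -1.0 * nll_paired_d_loss(
        state.dis_ct.forward_paired(batch_mr, batch_ct),
        state.dis_ct.forward_paired(batch_mr, fake_ct))
    _update(state, "dis_ct", d_ct, lr)

    fake_ct = state.syn_ct(batch_mr)
    adv_ct = nll_paired_g_loss(state.dis_ct.forward_paired(batch_mr, fake_ct))
    cyc_bwd = cycle_loss(batch_mr, state.syn_mr(fake_ct))
    vox_ct = voxel_l1_loss(batch_ct, fake_ct)
    _update(state, "syn_ct", adv_ct + lam * cyc_bwd + gamma * vox_ct, lr)

    breakdown = total_objective(float(adv_mr), float(adv_ct),
                                float(cyc_fwd) + float(cyc_bwd),
                                float(vox_mr) + float(vox_ct), cfg.weights)
    return breakdown, float(d_mr), float(d_ct)


# ---------------------------------------------------------------------------
# outer loop
# ---------------------------------------------------------------------------

def _active_phases(dataset: PhantomDataset, cfg: TrainConfig) -> tuple[bool, bool]:
    has_unpaired = bool(dataset.unpaired_ct) and bool(dataset.unpaired_mr)
    has_paired = bool(dataset.paired)
    unpaired = has_unpaired and cfg.mode in ("both", "unpaired")
    paired = has_paired and cfg.mode in ("both", "paired")
    if cfg.mode == "unpaired" and not has_unpaired:
        raise DataError("unpaired mode requested but unpaired pools are empty")
    if cfg.mode == "paired" and not has_paired:
        raise DataError("paired mode requested but the paired set is empty")
    if not (unpaired or paired):
        raise DataError("no usable data regime for training")
    return unpaired, paired


def train(dataset: PhantomDataset, cfg: TrainConfig,
          out_dir: str | None = None,
          resume_from: str | None = None) -> tuple[TrainingState, list[dict]]:
    """Run the alternating training loop to the iteration budget.

    Returns the final state and the per-step loss log (one row per phase
    step).  With ``out_dir`` set, writes ``training_log.csv``, periodic
    checkpoints and a final ``checkpoint_final.npz``.
    """
    if resume_from is not None:
        state, cfg = load_training_checkpoint(resume_from)
    else:
        state = init_state(cfg)
    run_unpaired, run_paired = _active_phases(dataset, cfg)

    log: list[dict] = []
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)

    sched_end = cfg.warm_iters + cfg.decay_iters
    it = state.iteration
    while it < cfg.budget:
        lr = lr_schedule(min(it, sched_end), cfg)
        if run_unpaired:
            for _ in range(cfg.niter):
                bct, bmr = prepare_unpaired_batch(
                    dataset.unpaired_ct, dataset.unpaired_mr, cfg, state.rng)
                breakdown, d_mr, d_ct = unpaired_phase_step(state, bct, bmr, cfg, lr)
                log.append(_row(it, "unpaired", d_mr, d_ct, breakdown, lr))
        if run_paired:
            for _ in range(cfg.niter):
                bct, bmr = prepare_paired_batch(dataset.paired, cfg, state.rng)
                breakdown, d_mr, d_ct = paired_phase_step(state, bct, bmr, cfg, lr)
                log.append(_row(it, "paired", d_mr, d_ct, breakdown, lr))
        it += 1
        state.iteration = it
        if out_dir and cfg.checkpoint_every and it % cfg.checkpoint_every == 0 \
                and it < cfg.budget:
            save_training_checkpoint(
                os.path.join(out_dir, f"checkpoint_{it:07d}.npz"), state, cfg)

    if out_dir:
        save_training_checkpoint(os.path.join(out_dir, "checkpoint_final.npz"),
                                 state, cfg)
        _write_log(os.path.join(out_dir, "training_log.csv"), log)
    return state, log


def _row(iteration: int, phase: str, d_mr: float, d_ct: float,
         b: LossBreakdown, lr: float) -> dict:
    return {"iteration": iteration, "phase": phase, "d_mr": d_mr, "d_ct": d_ct,
            "adv_mr": b.adv_mr, "adv_ct": b.adv_ct, "dual_cyc": b.dual_cyc,
            "voxel_l1": b.voxel_l1, "total": b.total, "lr": lr}


def _write_log(path: str, log: list[dict]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=LOG_COLUMNS)
        writer.writeheader()
        writer.writerows(log)
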