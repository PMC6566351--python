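import os

import numpy as np
import pytest

from mrgan import _autodiff as ad
from mrgan.errors import ConfigurationError, DataError
from mrgan.objectives import LossWeights, cycle_loss, voxel_l1_loss
from mrgan.training import (
    TrainConfig,
    init_state,
    lr_schedule,
    paired_phase_step,
    prepare_paired_batch,
    prepare_unpaired_batch,
    train,
    unpaired_phase_step,
)

from conftest import tiny_config


def _all_params(state):
    return [p.data.copy() for net in state.nets.values()
            for p in net.parameters()]


class TestLRSchedule:
    def test_published_anchor_points(self):
        cfg = TrainConfig()
        assert lr_schedule(0, cfg) == pytest.approx(2e-4)
        assert lr_schedule(100_000, cfg) == pytest.approx(2e-4)
        assert lr_schedule(200_000, cfg) == pytest.approx(1e-4)
        assert lr_schedule(300_000, cfg) == 0.0

    def test_closed_form_at_random_iterations(self):
        cfg = TrainConfig()
        rng = np.random.default_rng(0)
        for it in rng.integers(0, 300_001, size=1000):
            it = int(it)
            expect = 2e-4 if it < 100_000 else 2e-4 * (1 - (it - 100_000) / 200_000)
            assert lr_schedule(it, cfg) == pytest.approx(expect, abs=1e-12)

    def test_constant_during_warmup(self):
        cfg = TrainConfig(warm_iters=10, decay_iters=0)
        assert lr_schedule(10, cfg) == cfg.alpha

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            lr_schedule(300_001, TrainConfig())


class TestPhaseSteps:
    def _batches(self, state, cfg, dataset):
        bct, bmr = prepare_unpaired_batch(dataset.unpaired_ct,
                                          dataset.unpaired_mr, cfg, state.rng)
        pct, pmr = prepare_paired_batch(dataset.paired, cfg, state.rng)
        return bct, bmr, pct, pmr

    def test_zero_learning_rate_freezes_parameters(self, small_dataset):
        cfg = tiny_config()
        state = init_state(cfg)
        bct, bmr, pct, pmr = self._batches(state, cfg, small_dataset)
        before = _all_params(state)
        unpaired_phase_step(state, bct, bmr, cfg, lr=0.0)
        paired_phase_step(state, pct, pmr, cfg, lr=0.0)
        for b, a in zip(before, _all_params(state)):
            np.testing.assert_array_equal(b, a)

    def test_voxel_term_present_only_in_paired_phase(self, small_dataset):
        cfg = tiny_config(total_iters=2)
        _, log = train(small_dataset, cfg)
        assert len(log) == 4   # 2 iterations x 2 phases
        for row in log:
            if row["phase"] == "unpaired":
                assert row["voxel_l1"] == 0.0
            else:
                assert row["voxel_l1"] > 0.0

    def test_unpaired_step_descends_cycle_loss_with_frozen_discriminators(
            self, small_dataset):
        class StubDisc:
            def forward_unpaired(self, x):
                return ad.Tensor(np.full((1, 1, 4, 4), 0.5))

            def parameters(self):
                return []

        cfg = tiny_config()
        for lr in (1e-3, 1e-4, 1e-5):
            state = init_state(cfg)
            state.dis_mr = StubDisc()
            state.dis_ct = StubDisc()
            bct, bmr = prepare_unpaired_batch(small_dataset.unpaired_ct,
                                              small_dataset.unpaired_mr,
                                              cfg, state.rng)

            def dual_cycle():
                fwd = cycle_loss(bct, state.syn_ct(state.syn_mr(bct).detach()))
                bwd = cycle_loss(bmr, state.syn_mr(state.syn_ct(bmr).detach()))
                return float(fwd) + float(bwd)

            before = dual_cycle()
            unpaired_phase_step(state, bct, bmr, cfg, lr=lr)
            if dual_cycle() < before:
                break
        else:
            pytest.fail("cycle loss never decreased at any tested lr")

    def test_large_gamma_update_approaches_pure_l1_regression(self, small_dataset):
        """As γ grows the CT→MR generator's paired update converges to the
        update of a plain L1 regression toward the reference MR."""
        cfg0 = tiny_config()
        state = init_state(cfg0)
        pct, pmr = prepare_paired_batch(small_dataset.paired, cfg0, state.rng)

        def synmr_delta(weights_or_none):
            st = init_state(cfg0)
            before = [p.data.copy() for p in st.syn_mr.parameters()]
            if weights_or_none is None:   # pure L1 reference update
                for p in st.syn_mr.parameters():
                    p.grad = None
                loss = voxel_l1_loss(pmr, st.syn_mr(pct))
                loss.backward()
                st.optimizers["syn_mr"].step(cfg0.alpha)
            else:
                cfg = tiny_config(weights=weights_or_none)
                paired_phase_step(st, pct, pmr, cfg, lr=cfg.alpha)
            return np.concatenate([
                (p.data - b).ravel()
                for p, b in zip(st.syn_mr.parameters(), before)])

        ref = synmr_delta(None)

        def cosine(g):
            d = synmr_delta(LossWeights(lam=10.0, gamma=g))
            return float(d @ ref / (np.linalg.norm(d) * np.linalg.norm(ref)))

        cos = [cosine(g) for g in (1.0, 1e2, 1e4)]
        assert cos[0] < cos[2]
        assert cos[2] > 0.99


class TestTrainLoop:
    def test_seeded_runs_are_bit_identical(self, small_dataset):
        cfg = tiny_config(total_iters=3, seed=5)
        s1, log1 = train(small_dataset, cfg)
        s2, log2 = train(small_dataset, cfg)
        assert log1 == log2
        for a, b in zip(_all_params(s1), _all_params(s2)):
            np.testing.assert_array_equal(a, b)

    def test_log_bookkeeping_per_phase(self, small_dataset):
        cfg = tiny_config(total_iters=4)
        _, log = train(small_dataset, cfg)
        assert sum(r["phase"] == "unpaired" for r in log) == 4
        assert sum(r["phase"] == "paired" for r in log) == 4

    def test_resume_matches_uninterrupted_run(self, small_dataset, tmp_path):
        cfg = tiny_config(total_iters=6, checkpoint_every=3, seed=2)
        out = str(tmp_path / "full")
        _, log_full = train(small_dataset, cfg, out_dir=out)
        ckpt = os.path.join(out, "checkpoint_0000003.npz")
        assert os.path.exists(ckpt)
        _, log_resumed = train(small_dataset, cfg, resume_from=ckpt)
        tail = [r for r in log_full if r["iteration"] >= 3]
        assert log_resumed == tail

    def test_mode_gating_and_empty_regime_errors(self, small_dataset):
        cfg = tiny_config(total_iters=1, mode="unpaired")
        _, log = train(small_dataset, cfg)
        assert {r["phase"] for r in log} == {"unpaired"}
        cfg = tiny_config(total_iters=1, mode="paired")
        _, log = train(small_dataset, cfg)
        assert {r["phase"] for r in log} == {"paired"}
        from mrgan.phantom_data import PhantomDataset
        empty = PhantomDataset(paired=[], unpaired_ct=[], unpaired_mr=[],
                               ground_truth_map=small_dataset.ground_truth_map,
                               provenance=small_dataset.provenance)
        with pytest.raises(DataError):
            train(empty, tiny_config(total_iters=1))

    def test_training_log_csv_written(self, small_dataset, tmp_path):
        out = str(tmp_path / "run")
        train(small_dataset, tiny_config(total_iters=1), out_dir=out)
        with open(os.path.join(out, "training_log.csv")) as fh:
            lines = fh.read().strip().splitlines()
        assert lines[0].startswith("iteration,phase,")
        assert len(lines) == 3   # header + 2 phase rows


class TestAugmentSemantics:
    def test_paired_batch_shares_one_transform_draw(self, rng):
        from mrgan.preprocess import PairedSample
        sl = np.random.default_rng(1).uniform(0, 255, (32, 32))
        pairs = [PairedSample(ct=sl, mr=sl.copy(), subject_id="s")]
        cfg = tiny_config()
        for _ in range(5):
            bct, bmr = prepare_paired_batch(pairs, cfg, rng)
            np.testing.assert_array_equal(bct.data, bmr.data)

    def test_unpaired_batch_draws_independently(self, rng):
        sl = np.random.default_rng(1).uniform(0, 255, (32, 32))
        cfg = tiny_config()
        diffs = 0
        for _ in range(5):
            bct, bmr = prepare_unpaired_batch([sl], [sl.copy()], cfg, rng)
            diffs += not np.array_equal(bct.data, bmr.data)
        assert diffs > 0


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        TrainConfig(batch_size=0)
    with pytest.raises(ConfigurationError):
        TrainConfig(mode="sideways")
    with pytest.raises(ConfigurationError):
        TrainConfig(disc_variant="D9")
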