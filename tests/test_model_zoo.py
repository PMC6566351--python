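import numpy as np
import pytest

from mrgan import _autodiff as ad
from mrgan.errors import CheckpointError, ConfigurationError, ShapeError
from mrgan.model_zoo import (
    DISCRIMINATOR_VARIANTS,
    Discriminator,
    DiscriminatorVariant,
    Generator,
    GeneratorSpec,
    build_discriminator,
    build_generator,
    load_checkpoint,
    patch_score_map,
    restore_network,
    save_checkpoint,
)

TABLE_VARIANTS = {
    "D1": ((64,), (64, 128, 256, 512), (512, 1)),
    "D2": ((64, 64), (64, 128, 256, 512), (512, 512, 1)),
    "D3": ((64, 64), (64, 128, 256, 512), (512, 512, 512, 1)),
    "D4": ((64,), (128, 256, 512), (512, 1)),
    "D5": ((64,), (128, 256, 512), (1,)),
}


class TestGenerator:
    def test_default_spec_has_nine_residual_blocks(self):
        gen = build_generator()
        assert gen.spec.n_residual_blocks == 9
        assert len(gen.blocks) == 9

    @pytest.mark.parametrize("size", [64, 32])
    def test_shape_preserved(self, size, rng):
        gen = Generator(GeneratorSpec(base_filters=2, n_residual_blocks=1), rng)
        out = gen.forward(rng.normal(0, 0.3, (1, 1, size, size)))
        assert out.data.shape == (1, 1, size, size)

    def test_full_slice_shape_preserved_with_nine_blocks(self, rng):
        """256x256 input, nine residual blocks -> 256x256 output."""
        gen = Generator(GeneratorSpec(base_filters=2, n_residual_blocks=9), rng)
        out = gen.forward(np.zeros((1, 1, 256, 256)))
        assert out.data.shape == (1, 1, 256, 256)

    def test_output_bounded_by_tanh(self, rng):
        gen = Generator(GeneratorSpec(base_filters=2, n_residual_blocks=1), rng)
        out = gen.forward(rng.normal(0, 5.0, (1, 1, 16, 16)))
        assert np.all(out.data >= -1.0) and np.all(out.data <= 1.0)

    def test_indivisible_size_rejected(self, rng):
        gen = Generator(GeneratorSpec(base_filters=2, n_residual_blocks=1), rng)
        with pytest.raises(ShapeError):
            gen.forward(np.zeros((1, 1, 30, 30)))

    def test_resize_upsampling_variant_runs(self, rng):
        gen = Generator(GeneratorSpec(base_filters=2, n_residual_blocks=1,
                                      upsample="resize"), rng)
        assert gen.forward(np.zeros((1, 1, 16, 16))).data.shape == (1, 1, 16, 16)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorSpec(n_residual_blocks=0)


class TestDiscriminator:
    def test_catalog_matches_published_variant_grid(self):
        for name, (head, shared, tail) in TABLE_VARIANTS.items():
            v = DISCRIMINATOR_VARIANTS[name]
            assert (v.head_filters, v.shared_filters, v.tail_filters) == \
                (head, shared, tail)

    @pytest.mark.parametrize("name", sorted(TABLE_VARIANTS))
    def test_all_variants_build_and_run_on_64(self, name, rng):
        d = Discriminator(name, rng)
        x = rng.normal(0, 0.3, (1, 1, 64, 64))
        up = d.forward_unpaired(x)
        pp = d.forward_paired(x, x)
        for out in (up, pp):
            assert out.data.ndim == 4
            assert out.data.shape[2] < 64 and out.data.shape[3] < 64
            assert np.isfinite(out.data).all()
        assert np.all((pp.data > 0) & (pp.data < 1))   # sigmoid head
        # layer filter counts along the unpaired path, in order
        filters = tuple(c.weight.data.shape[0] for c in
                        d.unpaired_head + d.shared + d.unpaired_tail)
        head, shared, tail = TABLE_VARIANTS[name]
        assert filters == head + shared + tail

    def test_trunk_parameters_shared_between_regimes(self, rng):
        d = Discriminator("D5", rng)
        x = np.zeros((1, 1, 32, 32))
        # same conv objects (hence same parameter tensors) on both paths
        for conv in d.shared:
            assert any(p is conv.weight for p in d.parameters())
        before = [c.weight.data.copy() for c in d.shared]
        y = ad.mean(ad.square(d.forward_paired(ad.Tensor(x), ad.Tensor(x))))
        y.backward()
        # gradients from the PAIRED path land on the SHARED trunk weights
        assert all(c.weight.grad is not None for c in d.shared)
        for c, b in zip(d.shared, before):
            np.testing.assert_array_equal(c.weight.data, b)

    def test_forward_is_deterministic(self, rng):
        d = build_discriminator("D4", rng)
        x = rng.normal(0, 0.3, (1, 1, 32, 32))
        np.testing.assert_array_equal(patch_score_map(d, x),
                                      patch_score_map(d, x))

    def test_channel_mismatch_raises(self, rng):
        d = Discriminator("D5", rng)
        with pytest.raises(ShapeError):
            d.forward_unpaired(np.zeros((1, 2, 32, 32)))

    def test_custom_variant_and_validation(self, rng):
        v = DiscriminatorVariant("tiny", (4,), (8,), (4, 1))
        d = Discriminator(v, rng)
        assert d.forward_unpaired(np.zeros((1, 1, 16, 16))).data.shape[1] == 1
        with pytest.raises(ConfigurationError):
            DiscriminatorVariant("bad", (), (8,), (1,))


class TestCheckpoints:
    def test_roundtrip_preserves_parameters(self, tmp_path, rng):
        gen = Generator(GeneratorSpec(base_filters=2, n_residual_blocks=1), rng)
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(path, {"gen": gen}, meta={"iteration": 42})
        arrays, meta = load_checkpoint(path)
        assert meta["iteration"] == 42
        gen2 = Generator(GeneratorSpec(base_filters=2, n_residual_blocks=1),
                         np.random.default_rng(999))
        restore_network(gen2, arrays, "gen")
        for p1, p2 in zip(gen.parameters(), gen2.parameters()):
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_incompatible_restore_raises(self, tmp_path, rng):
        gen = Generator(GeneratorSpec(base_filters=2, n_residual_blocks=1), rng)
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(path, {"gen": gen})
        arrays, _ = load_checkpoint(path)
        other = Generator(GeneratorSpec(base_filters=4, n_residual_blocks=1),
                          rng)
        with pytest.raises(CheckpointError):
            restore_network(other, arrays, "gen")

    def test_non_checkpoint_file_rejected(self, tmp_path):
        path = str(tmp_path / "junk.npz")
        np.savez(path, a=np.zeros(3))
        with pytest.raises(CheckpointError):
            load_checkpoint(path)
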