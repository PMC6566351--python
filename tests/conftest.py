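import numpy as np
import pytest

from mrgan.model_zoo import DiscriminatorVariant, GeneratorSpec
from mrgan.phantom_data import PhantomParams, generate_dataset
from mrgan.training import TrainConfig

# desk-scale network: small enough that a training step runs in ~100 ms
TINY_GEN = GeneratorSpec(base_filters=4, n_residual_blocks=2)
TINY_DISC = DiscriminatorVariant("tiny", (8,), (16, 32), (16, 1))


def tiny_config(**kw) -> TrainConfig:
    base = dict(gen_spec=TINY_GEN, disc_variant=TINY_DISC, image_size=32,
                total_iters=2, seed=0)
    base.update(kw)
    return TrainConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    """32x32 phantoms: 4 paired + 6/6 unpaired, mild noise."""
    params = PhantomParams(image_size=32, noise_sd=2.0, seed=7)
    return generate_dataset(params, 4, 6, 6)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
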