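import numpy as np
import pytest

from parotidseg.model import ModelConfig, build_model
from parotidseg.phantoms import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def tiny_model_config():
    """Smallest sensible network: 32px input, depth 2, 4 base filters."""
    return ModelConfig(
        in_channels=3,
        input_size=32,
        depth=2,
        base_filters=4,
        encoder_block_allocation=[1, 1, 1],
        decoder_blocks_per_level=1,
        seed=0,
    )


@pytest.fixture(scope="session")
def tiny_spec():
    """Phantom on a (4, 32, 32) grid: fast to generate and to train on."""
    return PhantomSpec(grid_shape=(4, 32, 32), laterality="both", seed=3)


@pytest.fixture(scope="session")
def tiny_case(tiny_spec):
    return generate_phantom(tiny_spec, patient_id="tiny")


@pytest.fixture(scope="session")
def small_case():
    """Noise-free phantom on an (8, 64, 64) grid with bilateral tumors."""
    spec = PhantomSpec(grid_shape=(8, 64, 64), laterality="both",
                       noise_sd=0.0, seed=11)
    return generate_phantom(spec, patient_id="small")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_mask_pair(rng, max_grid=8, p=0.3):
    """A pair of random blobs on a shared small grid (test helper)."""
    shape = tuple(int(rng.integers(3, max_grid + 1)) for _ in range(3))
    a = rng.random(shape) < p
    b = rng.random(shape) < p
    return a, b


@pytest.fixture(scope="session")
def tiny_models_cache():
    """Session cache so expensive builds are shared across tests."""
    cache = {}

    def get(config: ModelConfig):
        key = repr(config)
        if key not in cache:
            cache[key] = build_model(config)
        return cache[key]

    return get
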