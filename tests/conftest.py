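import numpy as np
import pytest

from neurodg import (CohortSpec, ModelConfig, generate_cohort, make_parcellation)
from neurodg.train import TrainConfig, train_stage1

TINY_SHAPE = (16, 16, 16)


@pytest.fixture(scope="session")
def tiny_parcellation():
    return make_parcellation(TINY_SHAPE, 8, seed=1)


@pytest.fixture(scope="session")
def tiny_spec():
    return CohortSpec(
        n_per_class=(10, 8, 6),
        shape=TINY_SHAPE,
        n_regions=8,
        disease_regions=frozenset({2, 5}),
        effect_size=0.12,
        noise_sd=0.02,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec, tiny_parcellation):
    samples, effect_map = generate_cohort(tiny_spec, tiny_parcellation)
    return samples, effect_map


@pytest.fixture(scope="session")
def tiny_X_y(tiny_cohort):
    samples, _ = tiny_cohort
    X = np.stack([s.volume for s in samples])
    y = np.array([s.label for s in samples])
    return X, y


@pytest.fixture(scope="session")
def small_model_config():
    return ModelConfig(n_classes=3, encoder_channels=(4, 8), downsample_factor=4, seed=0)


@pytest.fixture(scope="session")
def trained_baseline(tiny_X_y, small_model_config):
    """A stage-1 baseline fitted on the tiny cohort (shared across tests)."""
    X, y = tiny_X_y
    est, history = train_stage1(
        X, y, small_model_config,
        TrainConfig(epochs=8, micro_batch=2, accumulation_steps=2,
                    learning_rate=3e-3, seed=0),
    )
    return est, history
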