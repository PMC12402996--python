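import numpy as np
import pytest

from synkin.config import SynthConfig
from synkin.synthetic import generate_cohort, generate_ratings, generate_visual_features


def small_config(**overrides) -> SynthConfig:
    defaults = dict(
        n_synergies=12,
        n_objects=12,
        n_raters=20,
        n_subjects=5,
        grid_shape=(14, 14, 14),
        n_rating_clusters=3,
        buffer_vox=2,
        seed=123,
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


@pytest.fixture
def cfg_small() -> SynthConfig:
    return small_config()


@pytest.fixture
def ratings_small(cfg_small):
    _, ratings = generate_ratings(cfg_small)
    return ratings


@pytest.fixture
def cohort_small(cfg_small, ratings_small):
    features, _ = generate_visual_features(cfg_small, ratings_small)
    return generate_cohort(cfg_small, ratings_small, visual_features=features)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
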