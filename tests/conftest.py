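import numpy as np
import pytest

from emoenc.design import build_lagged_design
from emoenc.features import default_feature_set
from emoenc.simulate import (
    GroundTruth,
    generate_block_schedule,
    generate_feature_timecourses,
)


@pytest.fixture(scope="session")
def feature_set():
    return default_feature_set()


@pytest.fixture(scope="session")
def movie_schedule():
    """The standard 13-block movie layout."""
    return generate_block_schedule(13, 30.0, seed=1)


@pytest.fixture(scope="session")
def movie_features(movie_schedule):
    return generate_feature_timecourses(movie_schedule, 2.0, 2.0, seed=7)


@pytest.fixture(scope="session")
def movie_design(movie_features):
    return build_lagged_design(movie_features)


@pytest.fixture()
def small_truth(feature_set):
    rng = np.random.default_rng(42)
    return GroundTruth(
        weights=0.15 * rng.standard_normal((feature_set.n_features, 3)),
        noise_sd=1.0,
        seed=42,
    )


def make_noise_sd_for_r2(design_X, weights_flat, r2):
    """Noise SD giving a target population R^2 for a known linear signal."""
    signal = design_X @ weights_flat
    var_sig = signal.var()
    return float(np.sqrt(var_sig * (1.0 - r2) / r2))
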