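"""Shared study configuration for the numbered analysis drivers.

One synthetic cohort, built deterministically from one seed, is shared
by all drivers: 11 children + 31 post-childhood participants watching
the 13-block movie, with a positive complex-emotion age gradient in the
true weights, a mild voice effect (music-block encoding at 85% of the
speech-block weights), and the childhood-DLPFC null built in.
"""

from pathlib import Path

import numpy as np

from emoenc.config import PipelineConfig
from emoenc.features import default_feature_set
from emoenc.simulate import (
    GroundTruth,
    default_cohort_spec,
    generate_cohort,
    sample_ground_truth_weights,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 0


def get_config() -> PipelineConfig:
    return PipelineConfig(
        complex_age_slope=0.01,   # true complex-weight gain per year
        voice_gain=0.85,
        noise_sd=2.0,
        n_perm=499,               # drivers use a reduced permutation count
        n_perm_inclusion=199,
        seed=SEED,
    )


def build_cohort(config: PipelineConfig | None = None):
    config = config or get_config()
    fset = default_feature_set(config.five_complex)
    rng = np.random.default_rng(config.seed)
    spec = default_cohort_spec(config.seed, config.complex_age_slope,
                               config.voice_gain)
    base = GroundTruth(
        sample_ground_truth_weights(rng, fset.n_features, len(config.lags),
                                    scale=config.weight_scale),
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    return generate_cohort(spec, base, seed=config.seed, feature_set=fset,
                           lags=config.lags, n_blocks=config.n_blocks,
                           block_dur=config.block_dur)
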