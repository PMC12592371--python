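import numpy as np
import pandas as pd
import pytest

from foldgene.encoder import EncoderConfig, EncoderState, _build, embed, reduce_pca
from foldgene.synthetic import ShapeFactors, make_covariates, render_cohort


@pytest.fixture(scope="session")
def two_pattern_cohort():
    """Separable cohort: half with a strong PCS, half without, n=400."""
    rng = np.random.default_rng(0)
    n = 400
    labels = rng.integers(0, 2, n)
    vals = pd.DataFrame({
        "pcs_strength": np.where(labels == 1, rng.normal(1.5, 0.4, n),
                                 rng.normal(-1.5, 0.4, n)),
        "cs_interruption": rng.normal(0, 1, n),
        "depth_scale": rng.normal(0, 0.5, n),
        "jitter": rng.normal(0, 1, n),
    })
    factors = ShapeFactors(values=vals)
    volumes = render_cohort(factors, seed=1)
    covariates = make_covariates(n, seed=2)
    return volumes, labels, covariates, factors


@pytest.fixture(scope="session")
def untrained_embedding(two_pattern_cohort):
    """PCA-reduced embedding of the two-pattern cohort under a random-init
    encoder (linear separability of planted patterns does not require
    training; tests that need a trained encoder train their own)."""
    volumes, labels, covariates, _ = two_pattern_cohort
    cfg = EncoderConfig(latent_dim=32, seed=0)
    backbone, projector = _build(cfg, volumes[0].grid.shape, np.random.default_rng(0))
    state = EncoderState(backbone, projector, cfg, volumes[0].grid.shape)
    return reduce_pca(embed(state, volumes))


def random_binary_volume(rng, shape=(8, 8, 8), density=0.2):
    return (rng.random(shape) < density).astype(np.uint8)
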