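import numpy as np
import pytest

from stromaqtl import SemConfig, SyntheticConfig, make_study


@pytest.fixture(scope="session")
def small_study():
    """Small planted study: 49 samples, 8 SNPs, 60 transcripts, 4 planted."""
    config = SyntheticConfig(
        n_samples=49, n_snps=8, n_transcripts=60, n_planted=4, hub_size=2,
        effect_size=1.5, resid_sd=1.0, seed=11,
    )
    return make_study(config)


@pytest.fixture(scope="session")
def short_sem_config():
    """Reduced-length chain for fast unit-level fits."""
    return SemConfig(n_iterations=400, burn_in=150, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
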