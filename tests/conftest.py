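import numpy as np
import pytest

from ehrclust import SimConfig, generate


@pytest.fixture(scope="session")
def small_cohort():
    """120-row cohort with 3 well-separated latent clusters."""
    cfg = SimConfig(
        n_patients=120,
        n_latent_clusters=3,
        vocab_size_diagnosis=60,
        vocab_size_operation=45,
        cluster_separation=0.9,
        seed=42,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with a high-risk planted cluster (log-odds +2)."""
    cfg = SimConfig(
        n_patients=1000,
        n_latent_clusters=4,
        cluster_separation=0.9,
        outcome_effects={0: 2.0},
        seed=7,
    )
    return generate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
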