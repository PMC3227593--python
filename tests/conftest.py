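import warnings

import numpy as np
import pytest

from adaptmap import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort with planted clinical + SNP effects, shared across tests."""
    cfg = SimConfig(
        n_subjects=600,
        n_features=8,
        n_categorical=1,
        block_structure=[],
        n_snps=300,
        n_causal_snps=2,
        snp_effect_size=3.0,
        planted_main_terms=[(0, 3.0), (1, 2.0)],
        planted_interaction_terms=[((0, 1), 1.5)],
        noise_sd=8.0,
        seed=4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort, geno, truth = simulate_cohort(cfg)
    return cfg, cohort, geno, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
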