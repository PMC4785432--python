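import numpy as np
import pandas as pd
import pytest

from mirlink import StudyConfig, generate_study, generate_target_db, generate_ppi


@pytest.fixture(scope="session")
def small_config():
    return StudyConfig(
        n_genes=200,
        n_mirnas=20,
        n_planted_regulators=3,
        targets_per_regulator=5,
        frac_de_genes=0.1,
        frac_de_mirnas=0.2,
        repression_strength=-1.0,
        noise_sd=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def small_annotations(small_study, small_config):
    study, truth = small_study
    tdb = generate_target_db(
        list(study.mirna_matrix.index),
        list(study.gene_matrix.index),
        truth,
        decoy_density=0.02,
        seed=small_config.seed + 1,
    )
    ppi = generate_ppi(list(study.gene_matrix.index), 0.02, seed=small_config.seed + 2)
    return tdb, ppi


@pytest.fixture
def rng():
    return np.random.default_rng(42)
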