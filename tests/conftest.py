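import numpy as np
import pytest

from cinneo.simulate import SimConfig, make_reference, sample_mutations, synthetic_signature_matrix
from cinneo.variants import load_table1_fixture, load_table2_fixture, load_table3_fixture


@pytest.fixture(scope="session")
def table2():
    return load_table2_fixture()


@pytest.fixture(scope="session")
def table3():
    return load_table3_fixture()


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def toy_reference():
    """Small random reference + transcript models shared across tests."""
    return make_reference(n_genes=6, cds_length_range=(300, 900), seed=11)


@pytest.fixture(scope="session")
def small_cohort(toy_reference):
    """Generated variant calls (9 samples) plus the generator truth table."""
    reference, transcripts = toy_reference
    cfg = SimConfig(
        seed=23,
        n_samples={"CIN1": 2, "CIN2": 2, "CIN3": 2, "CC": 3},
        mutation_mean={"CIN1": 6.45, "CIN2": 6.8, "CIN3": 9.67, "CC": 80.0},
    )
    sigs = synthetic_signature_matrix(seed=23)
    variants_by_sample, truth = sample_mutations(cfg, reference, transcripts, sigs)
    return cfg, variants_by_sample, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
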