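import pandas as pd
import pytest

from braintx.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    """Small but fully featured synthetic study used across test modules."""
    return SimConfig(
        n_genes_per_class={"protein_coding": 30, "lncRNA": 12, "pseudogene": 8},
        n_stable_genes=6,
        n_selective_genes=6,
        n_aei_genes=6,
        n_switch_genes=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def sim_data(sim_cfg):
    """(models, truth, expression, allele_counts, isoform_fpkm) bundle."""
    return simulate_all(sim_cfg)


@pytest.fixture(scope="session")
def models(sim_data):
    return sim_data[0]


@pytest.fixture(scope="session")
def truth(sim_data):
    return sim_data[1]


@pytest.fixture(scope="session")
def expr(sim_data):
    return sim_data[2]


@pytest.fixture(scope="session")
def allele_counts(sim_data):
    return sim_data[3]


@pytest.fixture(scope="session")
def iso_fpkm(sim_data):
    return sim_data[4]
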