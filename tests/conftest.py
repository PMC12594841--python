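import numpy as np
import pytest

from scregulon.grn import assemble_regulons, bootstrap_consensus
from scregulon.pipeline import preprocess_counts
from scregulon.regulons import regulon_set_from_table
from scregulon.synthetic import (
    SimulationConfig,
    simulate,
    truth_regulon_table,
    truth_signature_sets,
)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(default_config):
    return simulate(default_config)


@pytest.fixture(scope="session")
def em_sig(dataset):
    """Filtered + log-normalized matrix and its z-score signature matrix."""
    return preprocess_counts(dataset.counts)


@pytest.fixture(scope="session")
def signatures(em_sig):
    return em_sig[1]


@pytest.fixture(scope="session")
def truth_regulons(dataset):
    return regulon_set_from_table(truth_regulon_table(dataset.truth))


@pytest.fixture(scope="session")
def truth_sets(dataset, default_config):
    return truth_signature_sets(dataset.truth, default_config)


@pytest.fixture(scope="session")
def consensus_regulons(dataset, signatures):
    """Bootstrap-consensus network + assembled regulons on the default data."""
    net = bootstrap_consensus(signatures, sorted(dataset.truth.regulons), seed=1)
    return net, assemble_regulons(net, signatures)


@pytest.fixture()
def rng():
    return np.random.default_rng(1)
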