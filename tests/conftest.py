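import pytest

from cpdtools.refdata import cpd_primer_pair
from cpdtools.simulate import (
    amplicons_from_references,
    reference_database,
    simulate_references,
)


@pytest.fixture(scope="session")
def cpd_pair():
    return cpd_primer_pair()


@pytest.fixture(scope="session")
def sim_refs():
    """Small 3-taxon reference panel shared across pipeline tests."""
    return simulate_references(3, seed=7)


@pytest.fixture(scope="session")
def sim_templates(sim_refs):
    return amplicons_from_references(sim_refs.records, sim_refs.pair)


@pytest.fixture(scope="session")
def sim_refdb(sim_refs):
    return reference_database(sim_refs)
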