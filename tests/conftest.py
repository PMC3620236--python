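import pytest

from haplorisk import datasets


@pytest.fixture(scope="session")
def hap_table():
    return datasets.sardinian_haplotype_counts()


@pytest.fixture(scope="session")
def gen_table():
    return datasets.sardinian_genotype_counts()


@pytest.fixture(scope="session")
def transmission_tables():
    return datasets.sardinian_transmission_tables()


@pytest.fixture(scope="session")
def interaction_pairs():
    return datasets.sardinian_interaction_pairs()
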