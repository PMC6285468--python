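import pytest

from tumorflux.network import build_core_network
from tumorflux.params import load_params
from tumorflux.phenotypes import build_phenotype_table


@pytest.fixture(scope="session")
def net():
    return build_core_network()


@pytest.fixture(scope="session")
def params():
    return load_params()


@pytest.fixture(scope="session")
def fba_tables(net):
    """FBA-mode phenotype tables for all three scenarios (expensive)."""
    return {
        s: build_phenotype_table(net, s, mode="fba")
        for s in ("warburg", "reverse_warburg", "glutamine")
    }


@pytest.fixture(scope="session")
def ref_tables():
    """Reference (table-mode) phenotype tables."""
    return {
        s: build_phenotype_table(None, s, mode="table")
        for s in ("warburg", "reverse_warburg", "glutamine")
    }
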