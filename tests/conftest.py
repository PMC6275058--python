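import pytest

from cypcensus import make_genus, make_reference_library


@pytest.fixture(scope="session")
def library5():
    """Five synthetic families, one subfamily each, 400 aa, fixed seed."""
    return make_reference_library(n_families=5, subfamilies_per_family=1,
                                  length=400, seed=11)


@pytest.fixture(scope="session")
def library2():
    return make_reference_library(n_families=2, subfamilies_per_family=2,
                                  length=400, seed=7)


@pytest.fixture(scope="session")
def genus10():
    """Ten species, three planted P450s each, half inside clusters."""
    return make_genus(n_species=10, p450s_per_species=3,
                      in_cluster_fraction=0.5, seed=5)
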