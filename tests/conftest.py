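import pytest

from simbias.fixtures import frozen_fixtures
from simbias.fst import enumerate_fst_map
from simbias.perceptron import enumerate_perceptron_map
from simbias.rna import enumerate_rna_map


@pytest.fixture(scope="session")
def frozen():
    return frozen_fixtures()


@pytest.fixture(scope="session")
def rna_map_l12():
    """Exhaustive L=12 thermodynamic (Vienna) RNA map: 4^12 folds, the long fixture."""
    return enumerate_rna_map(12, folder="vienna")


@pytest.fixture(scope="session")
def fst_map_l20(frozen):
    """Exhaustive L=20 map of the frozen biased 5-state machine."""
    return enumerate_fst_map(frozen["machine"], 20)


@pytest.fixture(scope="session")
def perceptron_map_n5k2():
    """Exhaustive n=5, k=2 lattice perceptron parameter-function map."""
    return enumerate_perceptron_map(5, 2)
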