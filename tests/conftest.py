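import pytest

from moanet.network import Interaction, Interactome
from moanet.synthetic import make_mini_itp_fixture, planted_benchmark


@pytest.fixture
def chain_net():
    """Directed 2-edge chain MPL -> A -> B with signs (+1, -1)."""
    net = Interactome()
    net.add_edge(Interaction("MPL", "A", sign=1, relation="functional",
                             directed=True))
    net.add_edge(Interaction("A", "B", sign=-1, relation="functional",
                             directed=True))
    return net


@pytest.fixture(scope="session")
def mini_itp():
    return make_mini_itp_fixture()


@pytest.fixture(scope="session")
def small_benchmark():
    """A 50-node planted benchmark shared by trainer-level tests."""
    return planted_benchmark(seed=11, n_nodes=50)
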