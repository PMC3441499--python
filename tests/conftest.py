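import networkx as nx
import pytest

from netlab import network_io as nio
from netlab import synthetic_data as sd


@pytest.fixture(scope="session")
def default_fixture():
    """Records + annotations from the curated-export emulator at full scale."""
    spec = sd.FixtureSpec(rng_seed=11)
    records, annotations = sd.generate_string_fixture(spec)
    return spec, records, annotations


@pytest.fixture(scope="session")
def fixture_network(default_fixture):
    _, records, annotations = default_fixture
    return nio.build_network(records, annotations)


@pytest.fixture
def triangle():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C")])
    return g


@pytest.fixture
def small_oracle_graphs():
    """Assorted graphs with <= 12 nodes for brute-force comparisons."""
    graphs = {
        "path5": nx.path_graph(5),
        "cycle4": nx.cycle_graph(4),
        "cycle6": nx.cycle_graph(6),
        "star6": nx.star_graph(5),
        "k4": nx.complete_graph(4),
        "barbell": nx.barbell_graph(5, 1),
        "gnp10": nx.gnp_random_graph(10, 0.35, seed=3),
        "gnp12_sparse": nx.gnp_random_graph(12, 0.2, seed=9),
        "tree": nx.balanced_tree(2, 3),
    }
    return graphs
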