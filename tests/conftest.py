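import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def bridged_triangles() -> nx.Graph:
    """Two triangles joined by a single bridge edge; best Q = 5/14."""
    return nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])


#: Named connected graphs, all <= 8 nodes, over which the divisive algorithm
#: is validated against the exhaustive-search optimum.
SMALL_GRAPH_SUITE = {
    "path2": nx.path_graph(2),
    "path3": nx.path_graph(3),
    "path5": nx.path_graph(5),
    "cycle4": nx.cycle_graph(4),
    "cycle5": nx.cycle_graph(5),
    "cycle6": nx.cycle_graph(6),
    "star5": nx.star_graph(4),
    "clique4": nx.complete_graph(4),
    "clique5": nx.complete_graph(5),
    "bridged_triangles": bridged_triangles(),
    "barbell_3_1": nx.barbell_graph(3, 1),
    "two_cliques_ring": nx.ring_of_cliques(2, 4),
    "lollipop_4_2": nx.lollipop_graph(4, 2),
    "wheel6": nx.wheel_graph(5),
    "er7_seed42": nx.gnp_random_graph(7, 0.4, seed=42),
    "er7_seed3": nx.gnp_random_graph(7, 0.4, seed=3),
}


@pytest.fixture(scope="session")
def small_graphs() -> dict[str, nx.Graph]:
    for name, g in SMALL_GRAPH_SUITE.items():
        assert nx.is_connected(g), name
    return SMALL_GRAPH_SUITE
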