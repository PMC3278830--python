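import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from netenrich.fixtures import FixtureSpec, PlantedTerm, generate

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def triangle() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
    return g


@pytest.fixture
def path_plus_isolated() -> nx.Graph:
    """Path a-b-c plus isolated node d."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c")])
    g.add_node("d")
    return g


@pytest.fixture
def clique_fixture():
    """Six disjoint 4-cliques with one connected and one fragmented planted
    term of matched size."""
    spec = FixtureSpec(
        "disjoint-cliques",
        24,
        4,
        planted=(
            PlantedTerm("CONNECTED", 4, "connected"),
            PlantedTerm("FRAGMENTED", 4, "fragmented"),
        ),
        seed=3,
    )
    return generate(spec)
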