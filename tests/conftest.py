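import networkx as nx
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def c4():
    """4-cycle A-B-C-D with distinct vertex values: one essential loop."""
    g = nx.Graph([("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")])
    hits = {"A": -10.0, "B": -9.5, "C": -9.0, "D": -8.5}
    return g, hits


@pytest.fixture
def triangle():
    """Filled triangle: the clique complex kills the 3-cycle."""
    g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
    hits = {"A": -10.0, "B": -9.5, "C": -9.0}
    return g, hits
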