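import pytest

from moranfix import make_named_graph
from moranfix.graphs import NAMED_GRAPHS


@pytest.fixture(scope="session")
def motifs():
    """The six connected four-node networks, keyed by name."""
    return {name: make_named_graph(name, 4) for name in NAMED_GRAPHS}


@pytest.fixture(scope="session")
def diamond(motifs):
    return motifs["diamond"]
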