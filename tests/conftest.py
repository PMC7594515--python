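import numpy as np
import pytest

from pminr import NetworkTopology, insulin_resistance_fixture


@pytest.fixture(scope="session")
def fixture_topology() -> NetworkTopology:
    return insulin_resistance_fixture()


@pytest.fixture()
def tiny_topology() -> NetworkTopology:
    """4 nodes, 3 edges: A-B, B-C, C-D."""
    return NetworkTopology.from_named_edges([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
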