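import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

from rcdiff.model_core import BehaviorSet, Endowments

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def behaviors3() -> BehaviorSet:
    """The study's three test behaviors: costs (0.2, 0.5, 0.7), u = c."""
    return BehaviorSet.proportional([0.2, 0.5, 0.7])


@pytest.fixture
def path3() -> nx.Graph:
    return nx.path_graph(3)


@pytest.fixture
def star10() -> nx.Graph:
    """Star with center 0 and 10 leaves."""
    return nx.star_graph(10)


def rich_endowments(n: int, k: int, resource: float = 1.0,
                    threshold: float = 0.0) -> Endowments:
    """Degenerate endowments: uniform resource, uniform thresholds."""
    return Endowments(np.full(n, resource), np.full((n, k), threshold))
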