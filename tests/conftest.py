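import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from fblnet import BooleanNetwork, DirectedNetwork, toy_network_t1


@pytest.fixture
def t1() -> DirectedNetwork:
    """Hand-checkable fixture: a -> b <-> c -> d -> e."""
    return toy_network_t1()


@pytest.fixture
def mutual_negation() -> BooleanNetwork:
    """Two nodes inhibiting each other; each updates to the negation of its input.

    Full 4-state transition graph (node order a, b):
    00 -> 11 -> 00 (period-2 cycle); 01 -> 01 and 10 -> 10 (fixed points).
    """
    net = DirectedNetwork.from_edges([("a", "b"), ("b", "a")])
    return BooleanNetwork(
        net=net,
        inputs={"a": ("b",), "b": ("a",)},
        tables={"a": (1, 0), "b": (1, 0)},
    )
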