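import pytest

from booldelay.network import BooleanDelayNetwork, builtin_nfkb_network
from booldelay.rules import parse_rule
from booldelay.simulate import StimulusProtocol, simulate


@pytest.fixture(scope="session")
def nfkb():
    return builtin_nfkb_network()


@pytest.fixture(scope="session")
def tnf45_trace(nfkb):
    """Wild-type 45-minute TNF pulse on the bundled model, 720-minute horizon."""
    return simulate(nfkb, StimulusProtocol([("TNF", 0, 45)], 720))


@pytest.fixture
def toy_chain():
    """A -> B -> C relay chain with composable delays."""
    return BooleanDelayNetwork(
        nodes=["A", "B", "C"],
        rules={
            "B": parse_rule("A(t-2)", "B"),
            "C": parse_rule("3*B(t-3)", "C"),
        },
        stimulus_nodes=["A"],
        observable_nodes=["C"],
    )


def make_protocol(events, horizon=720):
    return StimulusProtocol(events, horizon)
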