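"""Structural analysis: relay collapse, kernel pathway and feedback routes."""

from booldelay import (
    BooleanDelayNetwork,
    builtin_nfkb_network,
    feedback_regulators,
    find_kernel,
    parse_rule,
    simplify,
)

network = builtin_nfkb_network()

kernel = find_kernel(network, sources=["TNF", "IL1", "LPS"], sinks=["NFkB"])
print("kernel pathway:", sorted(kernel))

regulators = feedback_regulators(network, "NFkB")
print("NF-kB feedback regulators:", sorted(regulators))

# relay collapse on a toy cascade: the interior node B has one input and one
# output, so it is removed and its delay folded into the downstream edge
toy = BooleanDelayNetwork(
    nodes=["A", "B", "C"],
    rules={"B": parse_rule("A(t-2)", "B"), "C": parse_rule("B(t-3)", "C")},
    stimulus_nodes=["A"],
    observable_nodes=["C"],
)
reduced = simplify(toy)
print("collapsed rule:", reduced.rules["C"].text())

# Every stimulus-to-output path runs through IKK -> IkBa -> NF-kB (the
# kernel); TNF, A20 and IL1 each close a feedback route from NF-kB back
# into the pathway; the toy chain A->B->C reduces to A(t-5) -> C, the two
# activation delays composing additively.
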