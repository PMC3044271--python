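"""Structural analysis of delayed Boolean networks.

Three operations, all on the signed pathway graph derived from the rules:

* :func:`simplify` — collapse relay nodes with a single input and a single
  output, composing activation delays additively along the removed path.
* :func:`find_kernel` — the kernel pathway: nodes through which every
  stimulus-to-output signal path must pass.
* :func:`feedback_regulators` — hub-mediated feedback routes: direct targets
  of a hub that close an elementary cycle back to it.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import networkx as nx

from .network import BooleanDelayNetwork
from .rules import And, EdgeTerm, Expression, Leaf, Not, Or, TransferRule

__all__ = [
    "to_pathway_graph",
    "simplify",
    "find_kernel",
    "feedback_regulators",
]


def to_pathway_graph(network: BooleanDelayNetwork) -> nx.DiGraph:
    """Signed directed graph of the network: edge sign is -1 for negated terms."""
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    for target, term in network.edges():
        g.add_edge(
            term.source,
            target,
            theta=term.theta,
            r=term.r,
            sign=-1 if term.negated else +1,
        )
    return g


def _replace_leaf(
    expr: Expression, source: str, new_term: EdgeTerm, wrap_not: bool, parity: bool
) -> Expression:
    """Replace the leaf reading *source*; ``wrap_not`` adds a NOT around it."""
    if isinstance(expr, Leaf):
        if expr.term.source != source:
            return expr
        term = EdgeTerm(
            source=new_term.source,
            theta=new_term.theta,
            r=new_term.r,
            negated=parity ^ wrap_not,
        )
        leaf = Leaf(term)
        return Not(leaf) if wrap_not else leaf
    if isinstance(expr, Not):
        return Not(_replace_leaf(expr.child, source, new_term, wrap_not, not parity))
    children = tuple(
        _replace_leaf(c, source, new_term, wrap_not, parity) for c in expr.children
    )
    return And(children) if isinstance(expr, And) else Or(children)


def simplify(network: BooleanDelayNetwork) -> BooleanDelayNetwork:
    """Collapse internal relay nodes with exactly one input and one output.

    A non-stimulus, non-observable node ``b`` with in-degree 1 and out-degree
    1 on the path ``a -> b -> c`` is removed and replaced by a single edge
    ``a -> c`` with ``theta = theta_ab + theta_bc``, ``r = r_bc`` and sign
    equal to the product of the two signs.  Branching or meeting nodes are
    preserved, and so is any node lying on a directed cycle: collapsing a
    feedback mediator (such as a dedicated negative regulator) would change
    the loop structure the reduction is meant to preserve.  The function
    iterates to a fixed point and is idempotent; already-simplified networks
    pass through unchanged.
    """
    net = network.copy()
    protected = set(net.stimulus_nodes) | set(net.observable_nodes)
    changed = True
    while changed:
        changed = False
        g = to_pathway_graph(net)
        cyclic = {
            n
            for comp in nx.strongly_connected_components(g)
            if len(comp) > 1
            for n in comp
        } | {n for n in g.nodes if g.has_edge(n, n)}
        out_count: dict[str, list[str]] = {}
        for target, term in net.edges():
            out_count.setdefault(term.source, []).append(target)
        for b in list(net.nodes):
            if b in protected or b in cyclic or b not in net.rules:
                continue
            in_terms = net.rules[b].terms
            if len(in_terms) != 1:
                continue
            targets = out_count.get(b, [])
            if len(targets) != 1:
                continue
            c = targets[0]
            if c == b:
                continue
            ab = in_terms[0]
            a = ab.source
            if a == b:
                continue
            rule_c = net.rules[c]
            bc = next(t for t in rule_c.terms if t.source == b)
            if a in rule_c.sources:
                continue  # collapsing would merge two edges between a and c
            composed = EdgeTerm(
                source=a,
                theta=ab.theta + bc.theta,
                r=bc.r,
                negated=False,  # flag fixed up inside _replace_leaf
            )
            new_expr = _replace_leaf(
                rule_c.expression, b, composed, wrap_not=ab.negated, parity=False
            )
            net.rules[c] = TransferRule(target=c, expression=new_expr)
            del net.rules[b]
            net.nodes.remove(b)
            changed = True
            break
    net.validate()
    return net


def find_kernel(
    network: BooleanDelayNetwork,
    sources: Iterable[str],
    sinks: Iterable[str],
) -> set[str]:
    """Nodes lying on every directed path from any source to any sink.

    Computed by enumerating simple paths on the pathway graph (the networks
    in scope are small).  Returns the empty set, with a warning, if no
    source-to-sink path exists.
    """
    sources = list(sources)
    sinks = list(sinks)
    if not sources or not sinks:
        raise ValueError("sources and sinks must be nonempty")
    g = to_pathway_graph(network)
    kernel: set[str] | None = None
    for s in sources:
        for k in sinks:
            for path in nx.all_simple_paths(g, s, k):
                nodes = set(path)
                kernel = nodes if kernel is None else kernel & nodes
    if kernel is None:
        warnings.warn("no source-to-sink path exists; kernel is empty")
        return set()
    return kernel


def feedback_regulators(
    network: BooleanDelayNetwork,
    hub: str,
    exclude_direct_two_cycles: bool = True,
) -> set[str]:
    """Direct targets of *hub* that mediate a feedback route back to it.

    Returns the hub's direct rule-targets that lie on at least one elementary
    directed cycle through the hub.  With ``exclude_direct_two_cycles``
    (default), a target whose only relationship is a direct two-node cycle
    with the hub (e.g. a transcription factor and its dedicated inhibitor)
    is excluded: that pair is the hub's self-regulatory loop, not a feedback
    route through the wider network.
    """
    if hub not in network.nodes:
        raise ValueError(f"unknown hub node {hub!r}")
    g = to_pathway_graph(network)
    direct_targets = {t for t in g.successors(hub) if t != hub}
    on_cycle: set[str] = set()
    for cycle in nx.simple_cycles(g):
        if hub in cycle:
            on_cycle.update(cycle)
    out = set()
    for t in direct_targets:
        if t not in on_cycle:
            continue
        if exclude_direct_two_cycles and g.has_edge(t, hub):
            continue
        out.add(t)
    return out
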