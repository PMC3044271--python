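"""Independent brute-force interpreter of the delayed-gate semantics.

This deliberately re-implements the published update rules as literally as
possible — per-edge state dictionaries, the activation condition checked by
scanning the explicit state history, the accumulator branches transcribed
from the pseudocode — sharing no code with the package's compiled simulator.
It exists solely as a cross-check oracle for tests.
"""

from __future__ import annotations

from booldelay.rules import And, Leaf, Not, Or


def _h(history, src, t, theta):
    """Activation condition: source ON continuously for the last theta minutes."""
    if t < theta:
        return 0
    return int(all(history[src][t - k] == 1 for k in range(1, theta + 1)))


def simulate_oracle(network, events, knockouts, horizon):
    """Replay the update rules minute by minute; returns {node: [bits]}."""
    knockouts = set(knockouts)
    x = {n: [0] * (horizon + 1) for n in network.nodes}

    def stim(n, t):
        return any(n == node and s <= t < e for node, s, e in events)

    for n in network.nodes:
        if stim(n, 0) and n not in knockouts:
            x[n][0] = 1

    # per-edge accumulator and gate state
    edges = {}
    for target, term in network.edges():
        edges[(target, term.source)] = {"tau": 0, "g": 0, "term": term}

    def eval_expr(expr, target):
        if isinstance(expr, Leaf):
            return edges[(target, expr.term.source)]["g"]
        if isinstance(expr, Not):
            return 1 - eval_expr(expr.child, target)
        if isinstance(expr, And):
            vals = [eval_expr(c, target) for c in expr.children]
            return int(all(vals))
        if isinstance(expr, Or):
            vals = [eval_expr(c, target) for c in expr.children]
            return int(any(vals))
        raise TypeError(expr)

    for t in range(1, horizon + 1):
        for (target, source), st in edges.items():
            term = st["term"]
            h = _h(x, source, t, term.theta)
            r = term.r
            if h == 1:
                if r >= 1:
                    st["tau"] = st["tau"] + r - 1
                    st["g"] = 1
                else:
                    st["tau"] = st["tau"] + 1
                    if st["tau"] >= -r:
                        st["g"] = 1
                        st["tau"] = st["tau"] - 1
                    else:
                        st["g"] = 0
            else:
                if r >= 1:
                    if st["tau"] > 0:
                        st["g"] = 1
                        st["tau"] = st["tau"] - 1
                    else:
                        st["g"] = 0
                else:
                    st["g"] = 0
                    st["tau"] = 0
        for n in network.nodes:
            if n in network.rules:
                v = eval_expr(network.rules[n].expression, n)
            else:
                v = 0
            if stim(n, t):
                v = 1
            if n in knockouts:
                v = 0
            x[n][t] = v
    return x
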