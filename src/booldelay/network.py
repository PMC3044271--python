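"""Network container, validation, JSON serialization and the bundled NF-kB model.

A :class:`BooleanDelayNetwork` holds an ordered set of named nodes and one
transfer rule per regulated node.  Nodes without a rule are pure inputs.
Stimulus nodes may additionally be driven by an exogenous protocol during
simulation (the exogenous signal is OR'd with the endogenous rule output, so
a node such as TNF can be both externally applied and transcriptionally
induced).  Observable nodes are the ones reported against experimental data.

The on-disk format is a small JSON dialect::

    {
      "nodes": ["IRAK1", ...],
      "stimulus_nodes": ["TNF", "IL1", "LPS"],
      "observable_nodes": ["IKK", "IkBa", "NFkB"],
      "rules": {"IRAK1": "5*IL1(t-1) OR 3*LPS(t-87)", ...}
    }

Rule strings use the same grammar the bundled model is written in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .rules import EdgeTerm, TransferRule, parse_rule

__all__ = [
    "BooleanDelayNetwork",
    "NetworkValidationError",
    "builtin_nfkb_network",
    "load_network",
    "save_network",
    "NFKB_KERNEL",
]


class NetworkValidationError(ValueError):
    """Raised when a network's rules and node declarations are inconsistent."""


@dataclass
class BooleanDelayNetwork:
    """A delayed Boolean network G = {V, E} with per-edge (theta, r) parameters."""

    nodes: list[str]
    rules: dict[str, TransferRule]
    stimulus_nodes: list[str] = field(default_factory=list)
    observable_nodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen = set()
        for n in self.nodes:
            if n in seen:
                raise NetworkValidationError(f"duplicate node name {n!r}")
            seen.add(n)
        for target, rule in self.rules.items():
            if target not in seen:
                raise NetworkValidationError(
                    f"rule target {target!r} is not a declared node"
                )
            if rule.target != target:
                raise NetworkValidationError(
                    f"rule stored under {target!r} has target {rule.target!r}"
                )
            for term in rule.terms:
                if term.source not in seen:
                    raise NetworkValidationError(
                        f"rule for {target!r} references undeclared node "
                        f"{term.source!r}"
                    )
        for group, name in (
            (self.stimulus_nodes, "stimulus"),
            (self.observable_nodes, "observable"),
        ):
            for n in group:
                if n not in seen:
                    raise NetworkValidationError(
                        f"{name} node {n!r} is not a declared node"
                    )

    # -- structure ----------------------------------------------------------

    @property
    def input_nodes(self) -> list[str]:
        """Nodes without a rule (pure inputs)."""
        return [n for n in self.nodes if n not in self.rules]

    def edges(self) -> list[tuple[str, EdgeTerm]]:
        """All (target, term) pairs, in node order then rule order."""
        out = []
        for n in self.nodes:
            if n in self.rules:
                for term in self.rules[n].terms:
                    out.append((n, term))
        return out

    def adjacency(self) -> set[tuple[str, str]]:
        """The derived edge set as (source, target) pairs (e_ij = 1)."""
        return {(term.source, target) for target, term in self.edges()}

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "stimulus_nodes": list(self.stimulus_nodes),
            "observable_nodes": list(self.observable_nodes),
            "rules": {t: r.text() for t, r in self.rules.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "BooleanDelayNetwork":
        nodes = list(data["nodes"])
        raw_rules = data.get("rules", {})
        rules = {}
        for target, text in raw_rules.items():
            if target in rules:
                raise NetworkValidationError(f"duplicate rule for {target!r}")
            rules[target] = parse_rule(text, target)
        return cls(
            nodes=nodes,
            rules=rules,
            stimulus_nodes=list(data.get("stimulus_nodes", [])),
            observable_nodes=list(data.get("observable_nodes", [])),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BooleanDelayNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.rules == other.rules
            and self.stimulus_nodes == other.stimulus_nodes
            and self.observable_nodes == other.observable_nodes
        )

    def copy(self) -> "BooleanDelayNetwork":
        return BooleanDelayNetwork.from_dict(self.to_dict())


def save_network(network: BooleanDelayNetwork, path: str | Path) -> None:
    Path(path).write_text(json.dumps(network.to_dict(), indent=2) + "\n")


def load_network(path: str | Path) -> BooleanDelayNetwork:
    with open(path) as fh:
        data = json.load(fh)
    return BooleanDelayNetwork.from_dict(data)


# ---------------------------------------------------------------------------
# the bundled NF-kB inflammation model
# ---------------------------------------------------------------------------

#: Kernel pathway of the bundled model: every stimulus-to-output signal path
#: passes through these three nodes.
NFKB_KERNEL = frozenset({"IKK", "IkBa", "NFkB"})

_NFKB_RULES = {
    "IRAK1": "5*IL1(t-1) OR 3*LPS(t-87)",
    "TAB1/TAB2/TAK1": "IRAK1(t-13) OR LPS(t-125)",
    "NIK": "TAB1/TAB2/TAK1(t-25) OR TNFR1(t-1)",
    "IKK": "TAB1/TAB2/TAK1(t-100) OR NIK(t-1)",
    "IkBa": "NOT 2*IKK(t-3) OR -62*NFkB(t-96)",
    "NFkB": "NOT IkBa(t-1)",
    "A20": "7*NFkB(t-107)",
    "IL1": "-62*NFkB(t-373)",
    "TNF": "-62*NFkB(t-69)",
    "TNFR1": "4*TNF(t-1) AND NOT A20(t-10)",
}

_NFKB_NODES = [
    "IRAK1",
    "TAB1/TAB2/TAK1",
    "NIK",
    "IKK",
    "IkBa",
    "NFkB",
    "A20",
    "IL1",
    "TNF",
    "TNFR1",
    "LPS",
]


def builtin_nfkb_network() -> BooleanDelayNetwork:
    """The fitted 10-rule NF-kB inflammation model bundled with the package.

    Eleven nodes: the three receptor-proximal inputs TNF, IL-1 and LPS (LPS is
    a pure input; TNF and IL1 are NF-kB-induced cytokines that can also be
    applied exogenously), the IRAK1 / TAB1-TAB2-TAK1 / NIK / TNFR1 relay, and
    the IKK -> IkBa -| NF-kB kernel with the negative regulator A20.
    Observable nodes are IKK, IkBa and NFkB.
    """
    rules = {t: parse_rule(text, t) for t, text in _NFKB_RULES.items()}
    return BooleanDelayNetwork(
        nodes=list(_NFKB_NODES),
        rules=rules,
        stimulus_nodes=["TNF", "IL1", "LPS"],
        observable_nodes=["IKK", "IkBa", "NFkB"],
    )
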