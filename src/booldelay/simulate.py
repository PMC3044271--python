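"""Synchronous minute-resolution simulation of a delayed Boolean network.

Semantics of one edge j -> i with parameters (theta, r):

* The edge's activation condition ``h`` is 1 exactly when the source has been
  ON continuously for at least ``theta`` minutes.
* Sustained response, ``r >= 1``: while ``h = 1`` the gate is open and the
  accumulator grows by ``r - 1`` per minute; when ``h`` drops the gate stays
  open while the accumulator drains at one minute per minute.  The sustain
  therefore scales with how long the input was held — a 45-minute input
  through an ``r = 4`` edge keeps its target on for 135 further minutes.
* Delayed response, ``r <= -1``: while ``h = 1`` the accumulator grows by one
  per minute and the gate opens only once it reaches ``|r|``; when ``h``
  drops the accumulator resets, so interrupted inputs make no delayed
  progress.

Updates are fully synchronous: at minute ``t`` every edge gate is advanced on
the minute ``t-1`` source states, then every node's gate tree is evaluated on
the fresh gate bits.  Exogenous stimulus is OR'd with a stimulus node's
endogenous rule output; knocked-out nodes are clamped to 0 at every minute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .network import BooleanDelayNetwork
from .rules import And, Expression, Leaf, Not

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap

__all__ = [
    "StimulusEvent",
    "StimulusProtocol",
    "EdgeState",
    "SimulationTrace",
    "edge_gate_update",
    "simulate",
    "activation_intervals",
]

_OP_AND = -1
_OP_OR = -2
_OP_NOT = -3


@dataclass(frozen=True)
class StimulusEvent:
    node: str
    start: int
    end: int
    level: int = 1


@dataclass(frozen=True)
class StimulusProtocol:
    """A stimulus schedule: each event holds a node at ``level`` on [start, end)."""

    events: tuple[StimulusEvent, ...]
    horizon: int

    def __init__(self, events: Iterable[StimulusEvent | tuple], horizon: int):
        evs = []
        for e in events:
            if not isinstance(e, StimulusEvent):
                e = StimulusEvent(*e)
            evs.append(e)
        if horizon < 1:
            raise ValueError(f"horizon must be >= 1, got {horizon}")
        for e in evs:
            if not (0 <= e.start < e.end <= horizon):
                raise ValueError(
                    f"event for {e.node!r}: need 0 <= start < end <= horizon, "
                    f"got [{e.start}, {e.end}) with horizon {horizon}"
                )
            if e.level not in (0, 1):
                raise ValueError(f"event for {e.node!r}: level must be 0 or 1")
        object.__setattr__(self, "events", tuple(evs))
        object.__setattr__(self, "horizon", int(horizon))

    def driven_nodes(self) -> set[str]:
        return {e.node for e in self.events if e.level == 1}


@dataclass
class EdgeState:
    """Per-edge dynamic state: accumulator tau, gate bit g, source on-run."""

    tau: int = 0
    g: int = 0
    on_run: int = 0


def edge_gate_update(
    state: EdgeState, source_on: int, theta: int, r: int
) -> tuple[EdgeState, int]:
    """Advance one edge gate by one minute on the current source bit.

    Returns the new state and the gate output bit.  This is the scalar
    reference form of the update the simulator applies to every edge.
    """
    if theta < 1:
        raise ValueError(f"theta must be >= 1, got {theta}")
    if r == 0:
        raise ValueError("r must be nonzero")
    on_run = state.on_run + 1 if source_on else 0
    tau = state.tau
    h = 1 if on_run >= theta else 0
    if r >= 1:
        if h:
            tau += r - 1
            g = 1
        elif tau > 0:
            g = 1
            tau -= 1
        else:
            g = 0
    else:
        if h:
            tau += 1
            if tau >= -r:
                g = 1
                tau -= 1
            else:
                g = 0
        else:
            g = 0
            tau = 0
    return EdgeState(tau=tau, g=g, on_run=on_run), g


@njit(cache=False)
def _step_kernel(
    horizon,
    edge_src,
    edge_theta,
    edge_r,
    prog,
    prog_start,
    prog_len,
    stim,
    ko,
    x,
):  # pragma: no cover - compiled; equivalence asserted against the oracle
    n_nodes = x.shape[0]
    n_edges = edge_src.shape[0]
    run = np.zeros(n_edges, dtype=np.int64)
    tau = np.zeros(n_edges, dtype=np.int64)
    g = np.zeros(n_edges, dtype=np.uint8)
    stack = np.zeros(64, dtype=np.uint8)
    for t in range(1, horizon + 1):
        for e in range(n_edges):
            s = x[edge_src[e], t - 1]
            if s:
                run[e] += 1
            else:
                run[e] = 0
            h = 1 if run[e] >= edge_theta[e] else 0
            r = edge_r[e]
            if r >= 1:
                if h:
                    tau[e] += r - 1
                    g[e] = 1
                elif tau[e] > 0:
                    g[e] = 1
                    tau[e] -= 1
                else:
                    g[e] = 0
            else:
                if h:
                    tau[e] += 1
                    if tau[e] >= -r:
                        g[e] = 1
                        tau[e] -= 1
                    else:
                        g[e] = 0
                else:
                    g[e] = 0
                    tau[e] = 0
        for n in range(n_nodes):
            ln = prog_len[n]
            if ln > 0:
                sp = 0
                for k in range(prog_start[n], prog_start[n] + ln):
                    tok = prog[k]
                    if tok >= 0:
                        stack[sp] = g[tok]
                        sp += 1
                    elif tok == _OP_AND:
                        sp -= 1
                        stack[sp - 1] = stack[sp - 1] & stack[sp]
                    elif tok == _OP_OR:
                        sp -= 1
                        stack[sp - 1] = stack[sp - 1] | stack[sp]
                    else:
                        stack[sp - 1] = 1 - stack[sp - 1]
                v = stack[0]
            else:
                v = np.uint8(0)
            if stim[n, t]:
                v = np.uint8(1)
            if ko[n]:
                v = np.uint8(0)
            x[n, t] = v


def _emit(expr: Expression, edge_index: Mapping[str, int], out: list[int]) -> None:
    if isinstance(expr, Leaf):
        out.append(edge_index[expr.term.source])
    elif isinstance(expr, Not):
        _emit(expr.child, edge_index, out)
        out.append(_OP_NOT)
    else:
        op = _OP_AND if isinstance(expr, And) else _OP_OR
        for i, child in enumerate(expr.children):
            _emit(child, edge_index, out)
            if i > 0:
                out.append(op)


class CompiledNetwork:
    """A network lowered to flat arrays for the stepping kernel.

    Edge parameter arrays are exposed (``edge_theta``, ``edge_r``) so a fitter
    can overwrite them between simulations without re-lowering the gate trees.
    """

    def __init__(self, network: BooleanDelayNetwork):
        self.network = network
        self.nodes = list(network.nodes)
        self.node_index = {n: i for i, n in enumerate(self.nodes)}
        edges = network.edges()
        self.edge_keys = [(t, term.source) for t, term in edges]
        self.edge_index = {k: i for i, k in enumerate(self.edge_keys)}
        self.edge_src = np.array(
            [self.node_index[term.source] for _, term in edges], dtype=np.int64
        )
        self.edge_theta = np.array([term.theta for _, term in edges], dtype=np.int64)
        self.edge_r = np.array([term.r for _, term in edges], dtype=np.int64)
        prog: list[int] = []
        starts = np.zeros(len(self.nodes), dtype=np.int64)
        lens = np.zeros(len(self.nodes), dtype=np.int64)
        for n in self.nodes:
            i = self.node_index[n]
            starts[i] = len(prog)
            if n in network.rules:
                per_edge = {
                    src: self.edge_index[(n, src)]
                    for tgt, src in self.edge_keys
                    if tgt == n
                }
                _emit(network.rules[n].expression, per_edge, prog)
            lens[i] = len(prog) - starts[i]
        self.prog = np.array(prog, dtype=np.int64)
        self.prog_start = starts
        self.prog_len = lens

    def set_parameters(self, params: Mapping[tuple[str, str], tuple[int, int]]) -> None:
        """Overwrite (theta, r) for the given (target, source) edges in place."""
        for key, (theta, r) in params.items():
            i = self.edge_index[key]
            if theta < 1 or r == 0:
                raise ValueError(f"edge {key}: invalid parameters ({theta}, {r})")
            self.edge_theta[i] = theta
            self.edge_r[i] = r

    def run(
        self,
        stim: np.ndarray,
        ko: np.ndarray,
        horizon: int,
        x0: np.ndarray | None = None,
    ) -> np.ndarray:
        x = np.zeros((len(self.nodes), horizon + 1), dtype=np.uint8)
        if x0 is not None:
            x[:, 0] = x0
        x[:, 0] |= stim[:, 0]
        x[:, 0][ko.astype(bool)] = 0
        _step_kernel(
            horizon,
            self.edge_src,
            self.edge_theta,
            self.edge_r,
            self.prog,
            self.prog_start,
            self.prog_len,
            stim,
            ko,
            x,
        )
        return x


@dataclass
class SimulationTrace:
    """Binary node x time matrix at 1-minute resolution (minute 0..horizon)."""

    nodes: list[str]
    states: np.ndarray
    protocol: StimulusProtocol
    knockouts: frozenset[str] = frozenset()

    def __getitem__(self, node: str) -> np.ndarray:
        try:
            i = self.nodes.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None
        return self.states[i]

    @property
    def horizon(self) -> int:
        return self.states.shape[1] - 1

    def to_frame(self):
        """Wide table: column ``t`` plus one 0/1 column per node."""
        import pandas as pd

        data = {"t": np.arange(self.states.shape[1])}
        for i, n in enumerate(self.nodes):
            data[n] = self.states[i]
        return pd.DataFrame(data)


def _stimulus_matrix(
    protocol: StimulusProtocol, node_index: Mapping[str, int], horizon: int
) -> np.ndarray:
    stim = np.zeros((len(node_index), horizon + 1), dtype=np.uint8)
    for e in protocol.events:
        if e.level == 1:
            stim[node_index[e.node], e.start : e.end] = 1
    return stim


def simulate(
    network: BooleanDelayNetwork,
    protocol: StimulusProtocol,
    knockouts: Iterable[str] = (),
    initial: Mapping[str, int] | None = None,
    compiled: CompiledNetwork | None = None,
) -> SimulationTrace:
    """Run the synchronous simulation under a stimulus protocol and knockouts.

    All nodes start OFF at minute 0 unless ``initial`` provides states.
    Knocked-out nodes are clamped to 0 at every minute.  Passing a prebuilt
    :class:`CompiledNetwork` skips the lowering step (used by the fitter).
    """
    knockouts = frozenset(knockouts)
    node_set = set(network.nodes)
    unknown = knockouts - node_set
    if unknown:
        raise ValueError(f"unknown knockout node(s): {sorted(unknown)}")
    stim_set = set(network.stimulus_nodes)
    for e in protocol.events:
        if e.node not in node_set:
            raise ValueError(f"stimulus event targets unknown node {e.node!r}")
        if e.node not in stim_set:
            raise ValueError(
                f"stimulus event targets non-stimulus node {e.node!r}"
            )
    driven = protocol.driven_nodes() & knockouts
    if driven:
        raise ValueError(
            f"contradictory experiment: node(s) {sorted(driven)} are both "
            "knocked out and driven by the stimulus protocol"
        )
    comp = compiled if compiled is not None else CompiledNetwork(network)
    horizon = protocol.horizon
    stim = _stimulus_matrix(protocol, comp.node_index, horizon)
    ko = np.zeros(len(comp.nodes), dtype=np.uint8)
    for n in knockouts:
        ko[comp.node_index[n]] = 1
    x0 = None
    if initial:
        x0 = np.zeros(len(comp.nodes), dtype=np.uint8)
        for n, v in initial.items():
            if n not in comp.node_index:
                raise ValueError(f"initial state for unknown node {n!r}")
            x0[comp.node_index[n]] = 1 if v else 0
    states = comp.run(stim, ko, horizon, x0)
    return SimulationTrace(
        nodes=list(comp.nodes),
        states=states,
        protocol=protocol,
        knockouts=knockouts,
    )


def activation_intervals(
    trace: SimulationTrace, node: str, burn_in: int = 0
) -> list[tuple[int, int]]:
    """Maximal on-runs of *node* as (first minute on, last minute on) pairs.

    Minutes earlier than ``burn_in`` are ignored, which can be used to drop
    the start-up transient of the all-off initial condition.
    """
    bits = trace[node]
    out: list[tuple[int, int]] = []
    start = None
    for t in range(burn_in, len(bits)):
        if bits[t] and start is None:
            start = t
        elif not bits[t] and start is not None:
            out.append((start, t - 1))
            start = None
    if start is not None:
        out.append((start, len(bits) - 1))
    return out
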