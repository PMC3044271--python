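"""Synthetic ground truth: random networks and densitometry-like trace data.

The generator emulates the kind of data a Western-blot time course yields: a
hidden delayed Boolean process sampled on a coarse minute grid, with each
sampled bit reported as a noisy continuous band intensity (Gaussian around an
off-level mu0 and an on-level mu1 > mu0, clipped at zero).  Noise acts on
intensity rather than on bits so that downstream binarization is exercised
the way real densitometry would exercise it.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binarize import IntensityProfile, binarize_profile
from .experiments import ExperimentSpec
from .network import BooleanDelayNetwork
from .rules import And, EdgeTerm, Leaf, Not, Or, TransferRule
from .simulate import CompiledNetwork, simulate

__all__ = [
    "SyntheticSpec",
    "generate_continuous_traces",
    "make_training_set",
    "random_network",
    "RecoveryStudy",
    "nfkb_recovery_study",
]


@dataclass
class SyntheticSpec:
    """Ground-truth network + experiments + densitometry noise model."""

    network: BooleanDelayNetwork
    experiments: list[ExperimentSpec]
    observed_nodes: list[str]
    grid: np.ndarray
    mu_off: float = 50.0
    mu_on: float = 140.0
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int64)
        if self.mu_on <= self.mu_off or self.mu_off < 0:
            raise ValueError("need mu_on > mu_off >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        unknown = set(self.observed_nodes) - set(self.network.nodes)
        if unknown:
            raise ValueError(f"observed nodes not in network: {sorted(unknown)}")


def generate_continuous_traces(
    spec: SyntheticSpec,
) -> dict[str, list[IntensityProfile]]:
    """Simulate the true network and emit noisy intensity profiles.

    Returns, per experiment name, one profile per observed node: the node's
    bit at each grid minute mapped to N(mu_bit, sigma^2) clipped at 0.
    """
    rng = np.random.default_rng(spec.seed)
    out: dict[str, list[IntensityProfile]] = {}
    compiled = CompiledNetwork(spec.network)
    for exp in spec.experiments:
        trace = simulate(
            spec.network, exp.protocol, exp.knockouts, compiled=compiled
        )
        profiles = []
        for node in spec.observed_nodes:
            bits = trace[node][spec.grid]
            mu = np.where(bits == 1, spec.mu_on, spec.mu_off)
            values = mu + rng.normal(0.0, spec.sigma, size=mu.shape)
            values = np.maximum(values, 0.0)
            profiles.append(IntensityProfile(node, spec.grid.copy(), values))
        out[exp.name] = profiles
    return out


def make_training_set(
    spec: SyntheticSpec, bins: int = 256
) -> list[ExperimentSpec]:
    """Generate traces, binarize them, and attach them as observations.

    With ``sigma = 0`` the recovered bits equal the true simulated bits
    exactly (the two intensity levels are separated by any threshold between
    them), closing the loop generator -> binarizer -> training data.
    """
    traces = generate_continuous_traces(spec)
    out = []
    for exp in spec.experiments:
        observations = [binarize_profile(p, bins=bins) for p in traces[exp.name]]
        out.append(exp.with_observations(observations))
    return out


@dataclass
class RecoveryStudy:
    """A ground-truth parameter-recovery benchmark for the staged GA fit."""

    truth: BooleanDelayNetwork
    true_params: dict
    stage1_training: list
    stage2_training: list
    kernel_nodes: list
    config_template: dict


def nfkb_recovery_study(
    horizon: int = 150, noise_sigma: float = 0.0, data_seed: int = 7
) -> RecoveryStudy:
    """The bundled staged-fit benchmark on the NF-kB network topology.

    The ground truth keeps the bundled wiring but uses minutes-scale
    parameters the reduced GA budget can resolve: the kernel carries
    IKK -| IkBa = (theta 3, r 2), NFkB -> IkBa = (theta 20, r -5) and
    IkBa -| NFkB = (theta 1, r 1), while every non-kernel edge is (1, 1) —
    the same convention the staged protocol itself assumes, so the stage-1
    model class contains the truth.  Four experiments are simulated (acute
    TNF, IL-1 and LPS pulses in wild type, plus the TNF pulse under A20
    knockout), observing IkBa and NFkB — the canonical blot/EMSA readouts —
    on a 1-minute grid.  Stage 1 trains on the three wild-type experiments;
    stage 2 adds the knockout.  ``config_template`` holds the reduced-budget
    GA settings matched to this study (population 150, 200 generations,
    theta in [1, 20], |r| <= 8, half-local mutation, up to 5 restarts).
    """
    from .experiments import ExperimentSpec
    from .gafit import apply_parameters, kernel_edges
    from .network import NFKB_KERNEL, builtin_nfkb_network
    from .simulate import StimulusProtocol

    base = builtin_nfkb_network()
    kernel_nodes = sorted(NFKB_KERNEL)
    inside, rest = kernel_edges(base, kernel_nodes)
    params = {e: (1, 1) for e in rest}
    params[("IkBa", "IKK")] = (3, 2)
    params[("IkBa", "NFkB")] = (20, -5)
    params[("NFkB", "IkBa")] = (1, 1)
    truth = apply_parameters(base, params)

    def ex(name, events, ko=()):
        return ExperimentSpec(
            name, StimulusProtocol(events, horizon), frozenset(ko)
        )

    experiments = [
        ex("tnf45-wt", [("TNF", 0, 45)]),
        ex("il1-15-wt", [("IL1", 0, 15)]),
        ex("lps45-wt", [("LPS", 0, 45)]),
        ex("tnf45-a20ko", [("TNF", 0, 45)], {"A20"}),
    ]
    spec = SyntheticSpec(
        network=truth,
        experiments=experiments,
        observed_nodes=["IkBa", "NFkB"],
        grid=np.arange(0, horizon + 1),
        sigma=noise_sigma,
        seed=data_seed,
    )
    training = {e.name: e for e in make_training_set(spec)}
    stage1 = [training[k] for k in ("tnf45-wt", "il1-15-wt", "lps45-wt")]
    stage2 = [training[k] for k in training]
    true_params = {
        (t, term.source): (term.theta, term.r) for t, term in truth.edges()
    }
    return RecoveryStudy(
        truth=truth,
        true_params=true_params,
        stage1_training=stage1,
        stage2_training=stage2,
        kernel_nodes=kernel_nodes,
        config_template=dict(
            population_size=150,
            generations=200,
            theta_range=(1, 20),
            r_max=8,
            local_mutation_prob=0.5,
            restarts=5,
            target_mse=0.0,
        ),
    )


def random_network(
    n_nodes: int,
    max_theta: int = 3,
    max_r: int = 3,
    seed: int = 0,
    feedback_prob: float = 0.3,
    not_prob: float = 0.3,
) -> BooleanDelayNetwork:
    """A random valid network: a DAG over n_nodes plus an optional feedback edge.

    Node ``N0`` is a pure input and the only stimulus node; the last node is
    observable.  Gate shapes (single term, NOT term, binary AND/OR) and edge
    parameters are sampled uniformly; duplicate (target, source) pairs never
    occur.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    names = [f"N{i}" for i in range(n_nodes)]
    rules: dict[str, TransferRule] = {}

    def term(src: str, negated: bool) -> EdgeTerm:
        theta = int(rng.integers(1, max_theta + 1))
        r = 0
        while r == 0:
            r = int(rng.integers(-max_r, max_r + 1))
        return EdgeTerm(src, theta, r, negated)

    def leaf(src: str) -> tuple:
        if rng.random() < not_prob:
            return Not(Leaf(term(src, True)))
        return Leaf(term(src, False))

    for i in range(1, n_nodes):
        n_parents = int(rng.integers(1, min(i, 2) + 1))
        parents = rng.choice(i, size=n_parents, replace=False)
        leaves = [leaf(names[int(p)]) for p in parents]
        if len(leaves) == 1:
            expr = leaves[0]
        else:
            gate = And if rng.random() < 0.5 else Or
            expr = gate(tuple(leaves))
        rules[names[i]] = TransferRule(names[i], expr)

    if n_nodes >= 3 and rng.random() < feedback_prob:
        # close a cycle: feed a late node back into an earlier regulated node
        tgt_i = int(rng.integers(1, n_nodes - 1))
        src_i = int(rng.integers(tgt_i + 1, n_nodes))
        tgt, src = names[tgt_i], names[src_i]
        if src not in rules[tgt].sources:
            old = rules[tgt].expression
            rules[tgt] = TransferRule(tgt, Or((old, leaf(src)))
                                      if not isinstance(old, Or)
                                      else Or(old.children + (leaf(src),)))

    return BooleanDelayNetwork(
        nodes=names,
        rules=rules,
        stimulus_nodes=[names[0]],
        observable_nodes=[names[-1]],
    )
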