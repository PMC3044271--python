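"""Genetic-algorithm estimation of edge parameters from binarized profiles.

Free edges are encoded as an integer chromosome of interleaved (theta, r)
genes.  Fitness is the mean squared error between simulated and observed
bits over every (experiment, node, timepoint) triple, so it lies in [0, 1]
and is 0 exactly when every sampled bit matches.  Selection is
roulette-wheel on inverse MSE, recombination is single-point crossover
(applied with probability ``crossover_rate``), mutation resamples each gene
independently within its declared range, and elitism copies the best
individuals unchanged into each next generation — which makes the
best-so-far history monotone non-increasing.

The two-stage protocol fits the kernel-pathway edges first (all other edges
pinned at theta = r = 1) against wild-type data, then freezes the kernel and
fits the remaining edges against the extended training set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .experiments import ExperimentSpec
from .network import BooleanDelayNetwork
from .simulate import CompiledNetwork, _stimulus_matrix

__all__ = [
    "GAConfig",
    "GAResult",
    "TwoStageResult",
    "FitnessEvaluator",
    "mse_fitness",
    "roulette_select",
    "crossover",
    "mutate",
    "random_chromosome",
    "run_ga",
    "kernel_edges",
    "two_stage_fit",
    "default_grid",
]

_EPSILON = 1e-6  # roulette weighting floor for zero-MSE individuals


def default_grid(horizon: int, step: int = 5) -> np.ndarray:
    """The default observation grid: every ``step`` minutes over the horizon."""
    return np.arange(0, horizon + 1, step, dtype=np.int64)


@dataclass(frozen=True)
class GAConfig:
    """GA hyperparameters; the defaults are the published settings."""

    population_size: int = 1000
    generations: int = 800
    crossover_rate: float = 1.0
    mutation_rate: float = 0.02
    elitism_count: int = 1
    seed: int = 0
    theta_range: tuple[int, int] = (1, 400)
    r_max: int = 100
    target_mse: float | None = None
    local_mutation_prob: float = 0.0
    restarts: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.crossover_rate <= 1.0):
            raise ValueError("crossover_rate must be in [0, 1]")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")
        if not (0.0 <= self.local_mutation_prob <= 1.0):
            raise ValueError("local_mutation_prob must be in [0, 1]")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.elitism_count < 1:
            raise ValueError("elitism_count must be >= 1")
        lo, hi = self.theta_range
        if not (1 <= lo <= hi):
            raise ValueError("theta_range must satisfy 1 <= lo <= hi")
        if self.r_max < 1:
            raise ValueError("r_max must be >= 1")
        if self.population_size < 2 or self.generations < 1:
            raise ValueError("population_size >= 2 and generations >= 1 required")


def random_chromosome(
    rng: np.random.Generator, config: GAConfig, n_edges: int
) -> np.ndarray:
    genes = np.empty(2 * n_edges, dtype=np.int64)
    lo, hi = config.theta_range
    genes[0::2] = rng.integers(lo, hi + 1, size=n_edges)
    k = rng.integers(0, 2 * config.r_max, size=n_edges)
    r = k - config.r_max
    r[r >= 0] += 1  # skip 0: r in [-r_max, -1] u [1, r_max]
    genes[1::2] = r
    return genes


def decode(
    chromosome: np.ndarray, free_edges: Sequence[tuple[str, str]]
) -> dict[tuple[str, str], tuple[int, int]]:
    """Map a chromosome onto its (target, source) -> (theta, r) parameters."""
    if len(chromosome) != 2 * len(free_edges):
        raise ValueError(
            f"chromosome length {len(chromosome)} does not decode onto "
            f"{len(free_edges)} free edges"
        )
    return {
        edge: (int(chromosome[2 * i]), int(chromosome[2 * i + 1]))
        for i, edge in enumerate(free_edges)
    }


class FitnessEvaluator:
    """Precompiled MSE fitness for one network / training set / edge choice.

    Simulation inputs (stimulus matrices, knockout masks, observation grids)
    are lowered once; each call overwrites only the free-edge parameters.
    Evaluations are memoized by chromosome bytes.
    """

    def __init__(
        self,
        network: BooleanDelayNetwork,
        free_edges: Sequence[tuple[str, str]],
        training_set: Sequence[ExperimentSpec],
        fixed_params: Mapping[tuple[str, str], tuple[int, int]] | None = None,
    ):
        if not training_set:
            raise ValueError("empty training set")
        if not free_edges:
            raise ValueError("no free edges to fit")
        self.compiled = CompiledNetwork(network)
        unknown = [e for e in free_edges if e not in self.compiled.edge_index]
        if unknown:
            raise ValueError(f"free edges not in network: {unknown}")
        self.free_edges = list(free_edges)
        if fixed_params:
            self.compiled.set_parameters(fixed_params)
        self._cases = []
        n_obs = 0
        for exp in training_set:
            if not exp.observations:
                raise ValueError(f"experiment {exp.name!r} has no observations")
            horizon = exp.protocol.horizon
            stim = _stimulus_matrix(exp.protocol, self.compiled.node_index, horizon)
            ko = np.zeros(len(self.compiled.nodes), dtype=np.uint8)
            for n in exp.knockouts:
                ko[self.compiled.node_index[n]] = 1
            obs = []
            for prof in exp.observations:
                row = self.compiled.node_index[prof.node]
                obs.append((row, prof.minutes, prof.bits.astype(np.int64)))
                n_obs += len(prof.bits)
            self._cases.append((stim, ko, horizon, obs))
        self._n_obs = n_obs
        self._cache: dict[bytes, float] = {}

    def __call__(self, chromosome: np.ndarray) -> float:
        key = chromosome.tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        self.compiled.set_parameters(decode(chromosome, self.free_edges))
        sq = 0
        for stim, ko, horizon, obs in self._cases:
            x = self.compiled.run(stim, ko, horizon)
            for row, minutes, bits in obs:
                diff = x[row, minutes].astype(np.int64) - bits
                sq += int((diff * diff).sum())
        mse = sq / self._n_obs
        self._cache[key] = mse
        return mse


def mse_fitness(
    network: BooleanDelayNetwork,
    chromosome: np.ndarray,
    training_set: Sequence[ExperimentSpec],
    free_edges: Sequence[tuple[str, str]],
    fixed_params: Mapping[tuple[str, str], tuple[int, int]] | None = None,
) -> float:
    """Mean squared bit error of a parameterization over a training set."""
    return FitnessEvaluator(network, free_edges, training_set, fixed_params)(
        np.asarray(chromosome, dtype=np.int64)
    )


def _roulette_weights(fitnesses: np.ndarray) -> np.ndarray:
    w = 1.0 / (fitnesses + _EPSILON)
    return w / w.sum()


def roulette_select(
    population: Sequence[np.ndarray],
    fitnesses: Sequence[float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample one parent with probability proportional to 1/(mse + epsilon)."""
    if len(population) == 0:
        raise ValueError("empty population")
    w = _roulette_weights(np.asarray(fitnesses, dtype=np.float64))
    return population[int(rng.choice(len(population), p=w))]


def crossover(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Single-point crossover at a uniform cut (cut 0 or L copies the parents)."""
    if len(a) != len(b):
        raise ValueError("chromosome length mismatch")
    cut = int(rng.integers(0, len(a) + 1))
    child_a = np.concatenate([a[:cut], b[cut:]])
    child_b = np.concatenate([b[:cut], a[cut:]])
    return child_a, child_b


def mutate(
    chromosome: np.ndarray, config: GAConfig, rng: np.random.Generator
) -> np.ndarray:
    """Mutate each gene independently with probability ``mutation_rate``.

    By default a mutated gene is resampled uniformly within its range.  With
    ``local_mutation_prob > 0`` a mutated gene instead takes, with that
    probability, a small step of 1-3 units (clipped to the range, skipping
    r = 0): delay genes are integers on a minute grid, so unit-scale moves
    are what align onsets and offsets exactly.
    """
    out = chromosome.copy()
    mask = rng.random(len(out)) < config.mutation_rate
    if not mask.any():
        return out
    n_edges = len(out) // 2
    fresh = random_chromosome(rng, config, n_edges)
    lo, hi = config.theta_range
    for gi in np.nonzero(mask)[0]:
        if config.local_mutation_prob and rng.random() < config.local_mutation_prob:
            step = int(rng.integers(1, 4)) * (1 if rng.random() < 0.5 else -1)
            v = int(out[gi]) + step
            if gi % 2 == 0:
                v = min(max(v, lo), hi)
            else:
                if v == 0:
                    v = 1 if step > 0 else -1
                v = min(max(v, -config.r_max), config.r_max)
            out[gi] = v
        else:
            out[gi] = fresh[gi]
    return out


@dataclass
class GAResult:
    best_params: dict[tuple[str, str], tuple[int, int]]
    best_mse: float
    history: list[float]
    best_chromosome: np.ndarray
    free_edges: list[tuple[str, str]]


def run_ga(
    network: BooleanDelayNetwork,
    free_edges: Sequence[tuple[str, str]],
    training_set: Sequence[ExperimentSpec],
    config: GAConfig,
    fixed_params: Mapping[tuple[str, str], tuple[int, int]] | None = None,
) -> GAResult:
    """Full GA loop: random init, roulette parents, crossover, mutation, elitism.

    Each run lasts ``config.generations`` generations (stopping early only
    when ``config.target_mse`` is reached).  With ``config.restarts > 1``
    the search is restarted from a fresh random population, with a seed
    derived deterministically from ``config.seed``, until the target is
    reached or the restarts are exhausted; the overall best is returned.
    The best-so-far history is monotone non-increasing across generations
    and restarts (the elitism guarantee).
    """
    evaluate = FitnessEvaluator(network, free_edges, training_set, fixed_params)
    n_edges = len(evaluate.free_edges)
    best = None
    best_fit = np.inf
    history: list[float] = []
    for restart in range(config.restarts):
        seed = (config.seed + 1000003 * restart) % (2**31)
        rng = np.random.default_rng(seed)
        pop = [
            random_chromosome(rng, config, n_edges)
            for _ in range(config.population_size)
        ]
        fits = np.array([evaluate(c) for c in pop])
        run_best = int(fits.argmin())
        if fits[run_best] < best_fit:
            best, best_fit = pop[run_best].copy(), float(fits[run_best])
        history.append(best_fit)
        for _ in range(config.generations):
            if config.target_mse is not None and best_fit <= config.target_mse:
                break
            order = np.argsort(fits, kind="stable")
            children = [pop[i].copy() for i in order[: config.elitism_count]]
            w = _roulette_weights(fits)
            while len(children) < config.population_size:
                i, j = rng.choice(len(pop), size=2, p=w)
                p1, p2 = pop[int(i)], pop[int(j)]
                if rng.random() < config.crossover_rate:
                    c1, c2 = crossover(p1, p2, rng)
                else:
                    c1, c2 = p1.copy(), p2.copy()
                children.append(mutate(c1, config, rng))
                if len(children) < config.population_size:
                    children.append(mutate(c2, config, rng))
            pop = children
            fits = np.array([evaluate(c) for c in pop])
            gen_best = int(fits.argmin())
            if fits[gen_best] < best_fit:
                best, best_fit = pop[gen_best].copy(), float(fits[gen_best])
            history.append(best_fit)
        if config.target_mse is not None and best_fit <= config.target_mse:
            break
    return GAResult(
        best_params=decode(best, evaluate.free_edges),
        best_mse=best_fit,
        history=history,
        best_chromosome=best,
        free_edges=list(evaluate.free_edges),
    )


def apply_parameters(
    network: BooleanDelayNetwork,
    params: Mapping[tuple[str, str], tuple[int, int]],
) -> BooleanDelayNetwork:
    """A copy of *network* with the given (target, source) -> (theta, r) set."""
    from .analysis import _replace_leaf
    from .rules import EdgeTerm, TransferRule

    out = network.copy()
    for (target, source), (theta, r) in params.items():
        rule = out.rules[target]
        if source not in rule.sources:
            raise ValueError(f"no edge {source!r} -> {target!r} in the network")
        new_term = EdgeTerm(source, theta, r)
        expr = _replace_leaf(rule.expression, source, new_term, False, False)
        out.rules[target] = TransferRule(target, expr)
    return out


def kernel_edges(
    network: BooleanDelayNetwork, kernel_nodes: Sequence[str]
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Split the network's edges into kernel-internal edges and the rest."""
    kernel = set(kernel_nodes)
    inside, rest = [], []
    for target, term in network.edges():
        (inside if target in kernel and term.source in kernel else rest).append(
            (target, term.source)
        )
    return inside, rest


@dataclass
class TwoStageResult:
    params: dict[tuple[str, str], tuple[int, int]]
    stage1: GAResult
    stage2: GAResult | None


def two_stage_fit(
    network: BooleanDelayNetwork,
    kernel_nodes: Sequence[str],
    stage1_training: Sequence[ExperimentSpec],
    stage2_training: Sequence[ExperimentSpec],
    config: GAConfig,
) -> TwoStageResult:
    """Kernel-first staged fit.

    Stage 1 optimizes only the edges between kernel nodes, with every other
    edge pinned at (theta, r) = (1, 1), against the stage-1 (wild-type)
    training set.  Stage 2 freezes the fitted kernel parameters and
    optimizes the remaining edges against the stage-2 (extended) set.  If
    the network has no non-kernel edges, stage 2 is a no-op and the result
    equals a plain single-stage fit of the kernel.
    """
    inside, rest = kernel_edges(network, kernel_nodes)
    if not inside:
        raise ValueError("no kernel-internal edges to fit in stage 1")
    stage1 = run_ga(
        network,
        inside,
        stage1_training,
        config,
        fixed_params={e: (1, 1) for e in rest},
    )
    if not rest:
        return TwoStageResult(dict(stage1.best_params), stage1, None)
    if not stage2_training:
        raise ValueError("stage-2 training set is empty")
    stage2 = run_ga(
        network,
        rest,
        stage2_training,
        config,
        fixed_params=stage1.best_params,
    )
    merged = {**stage1.best_params, **stage2.best_params}
    return TwoStageResult(merged, stage1, stage2)
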