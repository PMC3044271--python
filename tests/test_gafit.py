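"""GA fitting: fitness, operators, the full loop and the staged protocol."""

import numpy as np
import pytest

from booldelay.binarize import BinaryProfile
from booldelay.experiments import ExperimentSpec
from booldelay.gafit import (
    GAConfig,
    apply_parameters,
    crossover,
    kernel_edges,
    mse_fitness,
    mutate,
    roulette_select,
    run_ga,
    two_stage_fit,
)
from booldelay.network import BooleanDelayNetwork
from booldelay.rules import parse_rule
from booldelay.simulate import StimulusProtocol, simulate


@pytest.fixture
def chain3():
    """Stimulus -> M -> OUT chain with hidden true parameters."""
    return BooleanDelayNetwork(
        nodes=["S", "M", "OUT"],
        rules={
            "M": parse_rule("2*S(t-3)", "M"),
            "OUT": parse_rule("M(t-2)", "OUT"),
        },
        stimulus_nodes=["S"],
        observable_nodes=["OUT"],
    )


def chain_training(net, horizon=60):
    proto = StimulusProtocol([("S", 0, 20)], horizon)
    trace = simulate(net, proto)
    grid = np.arange(0, horizon + 1)
    obs = [BinaryProfile("OUT", grid, trace["OUT"][grid])]
    return [ExperimentSpec("pulse", proto, frozenset(), obs)]


class TestFitness:
    def test_perfect_prediction_scores_zero(self, chain3):
        training = chain_training(chain3)
        free = [("M", "S"), ("OUT", "M")]
        chrom = np.array([3, 2, 2, 1], dtype=np.int64)
        assert mse_fitness(chain3, chrom, training, free) == 0.0

    def test_complemented_observation_scores_one(self, chain3):
        training = chain_training(chain3)
        obs = training[0].observations[0]
        flipped = BinaryProfile(obs.node, obs.minutes, 1 - obs.bits)
        training = [training[0].with_observations([flipped])]
        chrom = np.array([3, 2, 2, 1], dtype=np.int64)
        assert mse_fitness(chain3, chrom, training, [("M", "S"), ("OUT", "M")]) == 1.0

    def test_mse_counts_mismatches(self, chain3):
        """3 flipped bits out of 10 sampled points -> MSE exactly 0.3."""
        proto = StimulusProtocol([("S", 0, 20)], 45)
        trace = simulate(chain3, proto)
        grid = np.arange(0, 50, 5)
        bits = trace["OUT"][grid].copy()
        bits[:3] ^= 1
        training = [ExperimentSpec("x", proto, frozenset(),
                                   [BinaryProfile("OUT", grid, bits)])]
        chrom = np.array([3, 2, 2, 1], dtype=np.int64)
        assert mse_fitness(chain3, chrom, training, [("M", "S"), ("OUT", "M")]) == 0.3

    def test_empty_training_set_rejected(self, chain3):
        with pytest.raises(ValueError, match="empty"):
            mse_fitness(chain3, np.array([1, 1]), [], [("M", "S")])


class TestSelection:
    def test_single_individual_always_selected(self):
        rng = np.random.default_rng(0)
        pop = [np.array([1, 1])]
        assert roulette_select(pop, [0.5], rng) is pop[0]

    def test_zero_mse_dominates(self):
        rng = np.random.default_rng(1)
        pop = [np.array([0]), np.array([1])]
        picks = sum(
            roulette_select(pop, [0.0, 1.0], rng) is pop[0] for _ in range(10_000)
        )
        assert picks > 9_990  # weight ratio ~1e6 : 1

    def test_equal_fitness_is_uniform(self):
        rng = np.random.default_rng(2)
        pop = [np.array([i]) for i in range(4)]
        counts = np.zeros(4)
        for _ in range(10_000):
            counts[int(roulette_select(pop, [0.2] * 4, rng)[0])] += 1
        # binomial 99.9% band around p=0.25
        assert np.all(np.abs(counts / 10_000 - 0.25) < 0.02)


class TestOperators:
    def test_boundary_cuts_copy_parents(self):
        a, b = np.arange(6), np.arange(6, 12)
        seen = set()
        rng = np.random.default_rng(3)
        for _ in range(200):
            c1, c2 = crossover(a, b, rng)
            assert len(c1) == len(c2) == 6
            seen.add(tuple(c1))
        assert tuple(a) in seen and tuple(b) in seen  # cut at 0 / L occurs

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            crossover(np.arange(4), np.arange(6), np.random.default_rng(0))

    def test_zero_mutation_rate_is_identity(self):
        cfg = GAConfig(population_size=2, generations=1, mutation_rate=0.0)
        c = np.array([5, -3, 7, 2], dtype=np.int64)
        assert np.array_equal(mutate(c, cfg, np.random.default_rng(0)), c)

    def test_full_mutation_stays_in_range_and_uniform(self):
        cfg = GAConfig(
            population_size=2, generations=1, mutation_rate=1.0,
            theta_range=(1, 8), r_max=4,
        )
        rng = np.random.default_rng(4)
        thetas = []
        for _ in range(4_000):
            c = mutate(np.array([1, 1], dtype=np.int64), cfg, rng)
            assert 1 <= c[0] <= 8
            assert c[1] != 0 and -4 <= c[1] <= 4
            thetas.append(int(c[0]))
        counts = np.bincount(thetas, minlength=9)[1:]
        from scipy.stats import chisquare

        assert chisquare(counts).pvalue > 1e-4

    def test_local_mutation_stays_in_range(self):
        cfg = GAConfig(
            population_size=2, generations=1, mutation_rate=1.0,
            theta_range=(1, 8), r_max=4, local_mutation_prob=1.0,
        )
        rng = np.random.default_rng(5)
        for _ in range(500):
            c = mutate(np.array([1, -4], dtype=np.int64), cfg, rng)
            assert 1 <= c[0] <= 8
            assert c[1] != 0 and -4 <= c[1] <= 4


class TestRunGA:
    def test_recovers_chain_parameters(self, chain3):
        training = chain_training(chain3)
        free = [("M", "S"), ("OUT", "M")]
        cfg = GAConfig(
            population_size=100, generations=100, seed=11,
            theta_range=(1, 10), r_max=5, target_mse=0.0, restarts=5,
        )
        res = run_ga(chain3, free, training, cfg)
        assert res.best_mse == 0.0

    def test_history_is_monotone_nonincreasing(self, chain3):
        training = chain_training(chain3)
        cfg = GAConfig(population_size=30, generations=25, seed=1,
                       theta_range=(1, 10), r_max=5)
        res = run_ga(chain3, [("M", "S"), ("OUT", "M")], training, cfg)
        assert all(a >= b for a, b in zip(res.history, res.history[1:]))
        assert len(res.history) == 26

    def test_same_seed_same_result(self, chain3):
        training = chain_training(chain3)
        cfg = GAConfig(population_size=30, generations=15, seed=7,
                       theta_range=(1, 10), r_max=5)
        r1 = run_ga(chain3, [("M", "S"), ("OUT", "M")], training, cfg)
        r2 = run_ga(chain3, [("M", "S"), ("OUT", "M")], training, cfg)
        assert r1.best_params == r2.best_params
        assert r1.history == r2.history


class TestTwoStage:
    def test_kernel_only_network_skips_stage_two(self, chain3):
        training = chain_training(chain3)
        cfg = GAConfig(population_size=60, generations=60, seed=3,
                       theta_range=(1, 10), r_max=5, target_mse=0.0)
        res = two_stage_fit(chain3, ["S", "M", "OUT"], training, training, cfg)
        assert res.stage2 is None
        direct = run_ga(chain3, [("M", "S"), ("OUT", "M")], training, cfg)
        assert res.params == direct.best_params

    def test_kernel_genes_frozen_through_stage_two(self, chain3):
        training = chain_training(chain3)
        cfg = GAConfig(population_size=40, generations=30, seed=5,
                       theta_range=(1, 10), r_max=5)
        res = two_stage_fit(chain3, ["M", "OUT"], training, training, cfg)
        for edge, val in res.stage1.best_params.items():
            assert res.params[edge] == val

    def test_empty_stage_two_training_rejected(self, chain3):
        cfg = GAConfig(population_size=10, generations=2)
        with pytest.raises(ValueError, match="stage-2"):
            two_stage_fit(chain3, ["M", "OUT"], chain_training(chain3), [], cfg)


def test_kernel_edges_partition(nfkb):
    inside, rest = kernel_edges(nfkb, ["IKK", "IkBa", "NFkB"])
    assert set(inside) == {("IkBa", "IKK"), ("IkBa", "NFkB"), ("NFkB", "IkBa")}
    assert len(inside) + len(rest) == 16


def test_apply_parameters_round_trip(nfkb):
    out = apply_parameters(nfkb, {("TNFR1", "TNF"): (9, 7)})
    term = next(t for t in out.rules["TNFR1"].terms if t.source == "TNF")
    assert (term.theta, term.r) == (9, 7)
    # negated partner untouched
    assert next(t for t in out.rules["TNFR1"].terms if t.source == "A20").negated
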