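"""Evolutionary operators and the full loop."""

import numpy as np
import pytest

import regexgp.gp as gp
from regexgp.gp import (
    FitnessEvaluator,
    GPConfig,
    crossover,
    evolve,
    init_population,
    mutate_individual,
    reduce_population,
    tournament_select,
)
from regexgp.model import Model, Rule
from regexgp.synthetic import generate_dataset, single_motif_profile


def flat_models(fitnesses, n_rules=None):
    out = []
    for i, f in enumerate(fitnesses):
        k = 1 if n_rules is None else n_rules[i]
        m = Model([Rule(j, pattern="K") for j in range(k)])
        m.fitness = f
        out.append(m)
    return out


class FakeRng:
    """Deterministic stand-in yielding queued draws."""

    def __init__(self, integer_queue):
        self.queue = list(integer_queue)

    def integers(self, *a, **k):
        return self.queue.pop(0)

    def random(self):
        return 0.0


class TestInitPopulation:
    def test_population_shape_and_zero_weights(self, rng):
        cfg = GPConfig(population_size=50, generations=1, seed=0)
        pop = init_population(cfg, rng)
        assert len(pop) == 50
        for ind in pop:
            assert 1 <= len(ind.rules) <= 8
            assert all(r.weight == 0.0 for r in ind.rules)
            assert all(r.tree.depth() <= 6 for r in ind.rules)

    def test_seeded_determinism(self):
        cfg = GPConfig(population_size=20, generations=1, seed=0)
        a = init_population(cfg, np.random.default_rng(3))
        b = init_population(cfg, np.random.default_rng(3))
        assert [[r.pattern_str for r in m.rules] for m in a] == [
            [r.pattern_str for r in m.rules] for m in b
        ]


class TestTournament:
    def test_k1_is_uniform_draw(self, rng):
        pop = flat_models([0.1, 0.9])
        picks = {id(tournament_select(pop, 1, rng)) for _ in range(200)}
        assert len(picks) == 2

    def test_unique_best_wins_when_sampled(self, rng):
        pop = flat_models([0.0, 0.0, 1.0, 0.0])
        for _ in range(50):
            winner = tournament_select(pop, len(pop) * 4, rng)
            assert winner.fitness == 1.0

    def test_selection_probability_matches_closed_form(self, rng):
        n, k, draws = 10, 5, 40_000
        pop = flat_models(np.linspace(0, 1, n).tolist())
        best = max(pop, key=lambda m: m.fitness)
        hits = sum(tournament_select(pop, k, rng) is best for _ in range(draws))
        expected = 1 - (1 - 1 / n) ** k
        se = np.sqrt(expected * (1 - expected) / draws)
        assert abs(hits / draws - expected) < 4 * se

    def test_unset_fitness_is_state_error(self, rng):
        pop = [Model([Rule(0, pattern="K")])]
        with pytest.raises(ValueError):
            tournament_select(pop, 2, rng)


class TestCrossover:
    def test_hand_constructed_cut(self):
        p1 = Model([Rule(i, pattern=p) for i, p in enumerate(["KA", "KC", "KD"])])
        p2 = Model([Rule(i, pattern=p) for i, p in enumerate(["RA", "RC"])])
        # valid (i,j) pairs are enumerated row-major; pick (1,1) directly
        valid = [
            (i, j)
            for i in range(4)
            for j in range(3)
            if not (i == 0 and j == 2)
            and not (j == 0 and i == 3)
            and not (i == 0 and j == 0)
            and not (i == 3 and j == 2)
        ]
        o1, o2 = crossover(p1, p2, FakeRng([valid.index((1, 1))]))
        assert [r.pattern_str for r in o1.rules] == ["KA", "RC"]
        assert [r.pattern_str for r in o2.rules] == ["RA", "KC", "KD"]

    def test_conservation_and_nonemptiness(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(1, 9), rng.integers(1, 9)
            p1 = Model([Rule(i, pattern="K") for i in range(n1)])
            p2 = Model([Rule(i, pattern="R") for i in range(n2)])
            o1, o2 = crossover(p1, p2, rng)
            assert len(o1) >= 1 and len(o2) >= 1
            assert len(o1) + len(o2) == n1 + n2  # no truncation at these sizes
            assert len({r.id for r in o1.rules}) == len(o1)

    def test_offspring_capped_at_max_rules(self, rng):
        p1 = Model([Rule(i, pattern="K") for i in range(28)])
        p2 = Model([Rule(i, pattern="R") for i in range(28)])
        for _ in range(50):
            o1, o2 = crossover(p1, p2, rng)
            assert len(o1) <= 30 and len(o2) <= 30

    def test_parents_unmodified(self, rng):
        p1 = Model([Rule(i, pattern="K") for i in range(3)])
        p2 = Model([Rule(i, pattern="R") for i in range(3)])
        crossover(p1, p2, rng)
        assert [r.pattern_str for r in p1.rules] == ["K", "K", "K"]


class TestMutateIndividual:
    def test_zero_rate_returns_identical_structure(self, rng):
        cfg = GPConfig(population_size=2, generations=1, mutation_probability=0.0)
        ind = Model([Rule(0, pattern="KK", weight=1.0)])
        out = mutate_individual(ind, cfg, rng)
        assert [r.pattern_str for r in out.rules] == ["KK"]

    def test_rule_count_stays_within_bounds(self, rng):
        cfg = GPConfig(population_size=2, generations=1, mutation_probability=1.0)
        full = init_population(GPConfig(population_size=2, generations=1), rng)[0]
        # inflate to the cap, then mutate heavily: the cap must hold
        while len(full.rules) < cfg.max_rules:
            full.rules.append(full.rules[0].copy())
            full.reassign_ids()
        single = init_population(GPConfig(population_size=2, generations=1), rng)[0]
        single.rules = single.rules[:1]
        for _ in range(100):
            assert 1 <= len(mutate_individual(full, cfg, rng).rules) <= 30
            assert len(mutate_individual(single, cfg, rng).rules) >= 1

    def test_all_outputs_valid_trees(self, rng):
        cfg = GPConfig(population_size=2, generations=1, mutation_probability=1.0)
        pop = init_population(GPConfig(population_size=30, generations=1), rng)
        for ind in pop:
            out = mutate_individual(ind, cfg, rng)
            for r in out.rules:
                if r.tree is not None:
                    r.tree.validate()
                    assert r.tree.depth() <= 6


class TestReducePopulation:
    def test_keeps_the_largest_fitnesses(self):
        pop = flat_models(np.linspace(0, 1, 15).tolist())
        kept = reduce_population(pop, 10)
        assert sorted(m.fitness for m in kept) == sorted(
            m.fitness for m in pop
        )[-10:]

    def test_ties_broken_by_parsimony(self):
        pop = flat_models([0.5] * 6, n_rules=[5, 1, 4, 2, 6, 3])
        kept = reduce_population(pop, 3)
        assert sorted(len(m.rules) for m in kept) == [1, 2, 3]

    def test_idempotent_at_target_size(self):
        pop = flat_models([0.3, 0.2, 0.1])
        assert reduce_population(pop, 3) == sorted(
            pop, key=lambda m: -m.fitness
        )

    def test_underfull_population_rejected(self):
        with pytest.raises(ValueError):
            reduce_population(flat_models([0.1]), 2)


@pytest.fixture(scope="module")
def smoke_run():
    ds = generate_dataset(50, effects=single_motif_profile(), rng=0)
    cfg = GPConfig(population_size=20, generations=5, cv_folds=3, seed=0)
    return evolve(cfg, ds)


class TestEvolve:
    def test_smoke_run_completes_and_logs(self, smoke_run):
        best, log = smoke_run
        assert len(log) == 5
        assert best.fitness is not None and len(best.rules) >= 1

    def test_elitism_makes_best_fitness_monotone(self, smoke_run):
        _, log = smoke_run
        trace = log.best_trace()
        assert all(b >= a - 1e-12 for a, b in zip(trace, trace[1:]))

    def test_random_mode_never_trains(self, monkeypatch):
        def boom(*a, **k):
            raise AssertionError("weight training invoked in random mode")

        monkeypatch.setattr(gp, "FitnessEvaluator", boom)
        ds = generate_dataset(40, rng=1)
        cfg = GPConfig(
            population_size=10, generations=3, seed=1, mode="random_weights"
        )
        best, log = evolve(cfg, ds)
        assert len(log) == 3
        assert all(-10 <= r.weight <= 10 for r in best.rules)


class TestFitnessEvaluator:
    def test_matches_unmemoized_kfold(self):
        """The memoizing evaluator must agree exactly with the plain
        k-fold implementation in the model layer."""
        from regexgp.model import kfold_fitness

        ds = generate_dataset(30, rng=4)
        model = Model([Rule(0, pattern="KK"), Rule(1, pattern="QS")])
        ev = FitnessEvaluator(ds, k=3, threshold=12.5, seed=9)
        ev.evaluate(model)
        fitness, validation = kfold_fitness(model, ds, k=3, threshold=12.5, seed=9)
        assert model.fitness == pytest.approx(fitness)
        assert model.validation_fitness == pytest.approx(validation)

    def test_training_calls_are_memoized(self):
        ds = generate_dataset(20, rng=5)
        ev = FitnessEvaluator(ds, k=2, seed=0)
        m1 = Model([Rule(0, pattern="KK")])
        m2 = Model([Rule(0, pattern="KK"), Rule(1, pattern="KK")])
        ev.evaluate(m1)
        calls = ev.train_calls
        ev.evaluate(m2)
        assert ev.train_calls == calls  # same pattern, no retraining
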