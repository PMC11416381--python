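"""The evolutionary engine.

Classic generational genetic programming over rule-list models:
tournament selection (k=5), one-point crossover on the rule lists,
two-tier mutation (whole-individual rule add/replace/delete, then
per-rule structural tree mutations), elitism, and truncation of the
doubled pool back to the population size each generation.  Fitness is
the k-fold mean training Pearson r under full per-fold weight
retraining (``trained`` mode) or plain Pearson r with uniformly random
weights (``random_weights`` control mode).

Because a rule's trained weight depends only on its pattern and the
fold it is trained on — never on the rest of the individual — the
engine memoizes match vectors and per-fold weights per unique pattern
string.  This makes population-scale evaluation tractable without
changing any result: evaluation is exactly the rule-independent
training the model layer defines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datasets import PeptideDataset
from .model import (
    MAX_RULES,
    Model,
    Rule,
    pearson,
    randomize_weights,
    score_matches,
    assign_folds,
)
from .motifs import build_motif_db
from .regex_tree import (
    MUTATION_KINDS,
    MatchTimeoutError,
    generate_random_tree,
    match_all,
    mutate_tree,
)

logger = logging.getLogger(__name__)


@dataclass
class GPConfig:
    """Hyper-parameters of one evolutionary run (defaults = study values)."""

    population_size: int = 1000
    generations: int = 300
    max_rules: int = MAX_RULES
    crossover_probability: float = 0.9
    mutation_probability: float = 0.1
    tournament_k: int = 5
    max_tree_depth: int = 6
    cv_folds: int = 6
    threshold: float = 12.5
    seed: int = 0
    mode: str = "trained"  # "trained" | "random_weights"
    initial_rules_min: int = 1
    initial_rules_max: int = 8
    redraw_folds_each_generation: bool = False

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for name in ("crossover_probability", "mutation_probability"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mode not in ("trained", "random_weights"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class GenerationStats:
    generation: int
    best_fitness: float
    mean_fitness: float
    best_validation: float
    best_n_rules: int


@dataclass
class EvolutionLog:
    entries: list[GenerationStats] = field(default_factory=list)

    def append(self, stats: GenerationStats) -> None:
        self.entries.append(stats)

    def __len__(self) -> int:
        return len(self.entries)

    def best_trace(self) -> list[float]:
        return [e.best_fitness for e in self.entries]

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame([vars(e) for e in self.entries]).to_csv(
            path, sep="\t", index=False
        )


class FitnessEvaluator:
    """Memoizing k-fold evaluator shared by a whole run.

    Caches, per unique pattern string: the boolean match vector over all
    training sequences, the trained weight per fold, and the weight on
    the full training set.  Fold assignment is fixed once per run so
    evaluation is deterministic and elitism's monotonicity holds.
    """

    def __init__(
        self,
        train: PeptideDataset,
        k: int = 6,
        threshold: float = 12.5,
        seed: int = 0,
    ):
        self.train = train
        self.k = k
        self.threshold = threshold
        self.sequences = train.sequences
        self.y = train.phenotypes
        self.folds = assign_folds(len(train), k, seed)
        self.fold_train_idx = [np.flatnonzero(self.folds != f) for f in range(k)]
        self.fold_val_idx = [np.flatnonzero(self.folds == f) for f in range(k)]
        self.fold_dbs = [
            build_motif_db(train.subset(idx.tolist()), threshold=threshold)
            for idx in self.fold_train_idx
        ]
        self.full_db = build_motif_db(train, threshold=threshold)
        self._cache: dict[str, tuple[np.ndarray, np.ndarray, float]] = {}
        self.train_calls = 0  # instrumentation: pattern trainings performed

    def _pattern_info(self, pattern: str) -> tuple[np.ndarray, np.ndarray, float]:
        info = self._cache.get(pattern)
        if info is not None:
            return info
        self.train_calls += 1
        matches: list[list[str]] = []
        for seq in self.sequences:
            try:
                matches.append(match_all(pattern, seq))
            except MatchTimeoutError:
                matches.append([])
        present = np.array([bool(m) for m in matches])
        fold_w = np.empty(self.k)
        for f in range(self.k):
            db = self.fold_dbs[f]
            fold_w[f] = sum(
                score_matches(matches[i], db) for i in self.fold_train_idx[f]
            )
        full_w = sum(score_matches(m, self.full_db) for m in matches)
        info = (present, fold_w, float(full_w))
        self._cache[pattern] = info
        return info

    def evaluate(self, model: Model) -> None:
        """Set ``fitness``/``validation_fitness`` and store full-training
        weights on the model's rules."""
        infos = [self._pattern_info(r.pattern_str) for r in model.rules]
        present = np.stack([i[0] for i in infos])  # rules × sequences
        fold_w = np.stack([i[1] for i in infos])  # rules × folds
        scores_per_fold = fold_w.T @ present  # folds × sequences
        r_train, r_val = [], []
        for f in range(self.k):
            ps = scores_per_fold[f]
            r_train.append(pearson(ps[self.fold_train_idx[f]], self.y[self.fold_train_idx[f]]))
            r_val.append(pearson(ps[self.fold_val_idx[f]], self.y[self.fold_val_idx[f]]))
        model.fitness = float(np.mean(r_train))
        model.validation_fitness = float(np.mean(r_val))
        for rule, info in zip(model.rules, infos):
            rule.weight = info[2]

    def finalize(self, model: Model) -> Model:
        """Retrain a model's weights once on the full training set."""
        for rule in model.rules:
            rule.weight = self._pattern_info(rule.pattern_str)[2]
        return model

    def pearson_on_full(self, model: Model) -> float:
        infos = [self._pattern_info(r.pattern_str) for r in model.rules]
        present = np.stack([i[0] for i in infos])
        weights = np.array([r.weight for r in model.rules])
        return pearson(weights @ present, self.y)


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------


def _random_rule(rule_id: int, cfg: GPConfig, rng: np.random.Generator) -> Rule:
    depth = int(rng.integers(2, cfg.max_tree_depth + 1))
    method = "full" if rng.random() < 0.5 else "grow"
    tree = generate_random_tree(depth, method, rng, depth_bound=cfg.max_tree_depth)
    return Rule(rule_id, tree=tree)


def init_population(cfg: GPConfig, rng: np.random.Generator) -> list[Model]:
    """Ramped half-and-half initialization: each individual gets a
    uniform 1..8 rules, trees drawn over depths 2..max with a 50/50
    full/grow mix, all weights zero."""
    population = []
    for _ in range(cfg.population_size):
        n_rules = int(rng.integers(cfg.initial_rules_min, cfg.initial_rules_max + 1))
        rules = [_random_rule(i, cfg, rng) for i in range(n_rules)]
        population.append(Model(rules, max_rules=cfg.max_rules))
    return population


def _rank_key(model: Model) -> tuple[float, int]:
    """Sort key: higher fitness first, parsimony (fewer rules) on ties;
    list position breaks remaining ties deterministically."""
    if model.fitness is None:
        raise ValueError("individual has no fitness set")
    return (-model.fitness, len(model.rules))


def tournament_select(
    population: list[Model], k: int, rng: np.random.Generator
) -> Model:
    """Best of ``k`` uniform draws with replacement."""
    if not population:
        raise ValueError("population is empty")
    picks = rng.integers(len(population), size=k)
    best = min(sorted(picks), key=lambda i: (_rank_key(population[i]), i))
    return population[best]


def crossover(
    p1: Model, p2: Model, rng: np.random.Generator
) -> tuple[Model, Model]:
    """One-point crossover on the rule lists.

    Cut points ``i ∈ 0..|p1|`` and ``j ∈ 0..|p2|`` are drawn uniformly
    from the combinations that leave both offspring non-empty and do not
    reproduce both parents verbatim; offspring are
    ``p1[:i] + p2[j:]`` and ``p2[:j] + p1[i:]``, truncated from the tail
    if they exceed the rule cap, with ids reassigned.
    """
    if len(p1) == 0 or len(p2) == 0:
        raise ValueError("parents must have at least one rule")
    n1, n2 = len(p1), len(p2)
    valid = [
        (i, j)
        for i in range(n1 + 1)
        for j in range(n2 + 1)
        if not (i == 0 and j == n2)  # o1 empty
        and not (j == 0 and i == n1)  # o2 empty
        and not (i == 0 and j == 0)  # both parents reproduced
        and not (i == n1 and j == n2)
    ]
    if not valid:
        # two single-rule parents can only be recreated or swapped;
        # degrade gracefully to copies
        return p1.copy(), p2.copy()
    i, j = valid[rng.integers(len(valid))]
    cap = p1.max_rules

    def make(rules: list[Rule]) -> Model:
        rules = [r.copy() for r in rules[:cap]]
        for new_id, rule in enumerate(rules):
            rule.id = new_id
        return Model(rules, max_rules=cap)

    o1 = make(p1.rules[:i] + p2.rules[j:])
    o2 = make(p2.rules[:j] + p1.rules[i:])
    return o1, o2


def mutate_individual(
    ind: Model, cfg: GPConfig, rng: np.random.Generator
) -> Model:
    """Two-tier mutation; always returns a (possibly identical) copy.

    With probability ``mutation_probability`` one whole-individual
    mutation is applied — add a random rule (if below the cap), replace
    a rule, or delete a rule (if at least two remain).  Then each rule
    independently receives, with the same probability, one structural
    tree mutation drawn uniformly from the four kinds.
    """
    out = ind.copy()
    out.fitness = None
    out.validation_fitness = None
    pm = cfg.mutation_probability
    if pm > 0 and rng.random() < pm:
        options = ["replace"]
        if len(out.rules) < cfg.max_rules:
            options.append("add")
        if len(out.rules) >= 2:
            options.append("delete")
        choice = options[rng.integers(len(options))]
        if choice == "add":
            out.rules.append(_random_rule(len(out.rules), cfg, rng))
        elif choice == "replace":
            pos = int(rng.integers(len(out.rules)))
            out.rules[pos] = _random_rule(out.rules[pos].id, cfg, rng)
        else:
            del out.rules[int(rng.integers(len(out.rules)))]
    for pos, rule in enumerate(out.rules):
        if pm > 0 and rng.random() < pm and rule.tree is not None:
            kind = MUTATION_KINDS[rng.integers(len(MUTATION_KINDS))]
            out.rules[pos] = Rule(rule.id, tree=mutate_tree(rule.tree, kind, rng))
    out.reassign_ids()
    return out


def reduce_population(population: list[Model], size: int) -> list[Model]:
    """Keep the ``size`` best individuals (truncation).  Ties resolved
    by parsimony, then original position — deterministic."""
    if len(population) < size:
        raise ValueError(f"cannot reduce {len(population)} individuals to {size}")
    order = sorted(range(len(population)), key=lambda i: (_rank_key(population[i]), i))
    return [population[i] for i in order[:size]]


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------


def evolve(
    cfg: GPConfig,
    dataset: PeptideDataset,
    evaluator: FitnessEvaluator | None = None,
) -> tuple[Model, EvolutionLog]:
    """Run the full evolutionary loop on a labeled training set.

    Per generation: copy the elite, fill an offspring pool from
    tournament-selected parents (crossover with probability
    ``crossover_probability``, otherwise copies), mutate the offspring,
    evaluate them, and truncate the doubled pool back to the population
    size.  Returns the best-ever individual with its weights retrained
    on the full training set, and the per-generation log.

    In ``random_weights`` mode no weight training happens at all:
    weights start uniform in [−10, 10] and are perturbed each
    generation with the mutation rate, fitness being plain Pearson r on
    the training set.
    """
    rng = np.random.default_rng(cfg.seed)
    trained_mode = cfg.mode == "trained"
    if evaluator is None and trained_mode:
        evaluator = FitnessEvaluator(
            dataset, k=cfg.cv_folds, threshold=cfg.threshold, seed=cfg.seed
        )

    def eval_random(ind: Model) -> None:
        scores = np.array(
            [
                sum(
                    r.weight
                    for r in ind.rules
                    if _present(r.pattern_str, seq)
                )
                for seq in dataset.sequences
            ]
        )
        ind.fitness = pearson(scores, dataset.phenotypes)
        ind.validation_fitness = ind.fitness

    _present_cache: dict[tuple[str, str], bool] = {}

    def _present(pattern: str, seq: str) -> bool:
        key = (pattern, seq)
        hit = _present_cache.get(key)
        if hit is None:
            try:
                hit = bool(match_all(pattern, seq))
            except MatchTimeoutError:
                hit = False
            _present_cache[key] = hit
        return hit

    def evaluate(ind: Model) -> None:
        if trained_mode:
            evaluator.evaluate(ind)
        else:
            eval_random(ind)

    population = init_population(cfg, rng)
    if not trained_mode:
        for ind in population:
            randomize_weights(ind, rng, p=1.0)
    for ind in population:
        evaluate(ind)

    best_ever = min(population, key=_rank_key).copy()
    log = EvolutionLog()

    for gen in range(cfg.generations):
        elite = min(population, key=_rank_key)
        offspring: list[Model] = []
        while len(offspring) < cfg.population_size:
            pa = tournament_select(population, cfg.tournament_k, rng)
            pb = tournament_select(population, cfg.tournament_k, rng)
            if rng.random() < cfg.crossover_probability:
                o1, o2 = crossover(pa, pb, rng)
            else:
                o1, o2 = pa.copy(), pb.copy()
            offspring.extend([o1, o2])
        offspring = offspring[: cfg.population_size]
        offspring = [mutate_individual(o, cfg, rng) for o in offspring]
        if not trained_mode:
            # control mode: random exploration of weights instead of training.
            # Offspring inherit parental weights through crossover; rules
            # freshly created by mutation (weight still 0) are initialized
            # randomly, then every rule is perturbed at the mutation rate.
            for o in offspring:
                for rule in o.rules:
                    if rule.weight == 0.0:
                        rule.weight = float(rng.uniform(-10.0, 10.0))
                randomize_weights(o, rng, p=cfg.mutation_probability)
            survivors = []
            for ind in population:
                if ind is elite:
                    survivors.append(ind)
                    continue
                perturbed = ind.copy()
                randomize_weights(perturbed, rng, p=cfg.mutation_probability)
                eval_random(perturbed)
                survivors.append(perturbed)
            population = survivors
        for o in offspring:
            evaluate(o)
        population = reduce_population(population + offspring, cfg.population_size)
        current_best = min(population, key=_rank_key)
        if current_best.fitness > best_ever.fitness or (
            current_best.fitness == best_ever.fitness
            and len(current_best.rules) < len(best_ever.rules)
        ):
            best_ever = current_best.copy()
        log.append(
            GenerationStats(
                generation=gen,
                best_fitness=current_best.fitness,
                mean_fitness=float(np.mean([m.fitness for m in population])),
                best_validation=current_best.validation_fitness,
                best_n_rules=len(current_best.rules),
            )
        )
        if cfg.redraw_folds_each_generation and trained_mode:
            evaluator = FitnessEvaluator(
                dataset,
                k=cfg.cv_folds,
                threshold=cfg.threshold,
                seed=int(rng.integers(2**31 - 1)),
            )

    best = best_ever.copy()
    if trained_mode:
        best = evaluator.finalize(best)
    return best, log
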