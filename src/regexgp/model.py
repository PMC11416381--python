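"""Rule-list models: weight training, prediction, Pearson fitness.

A model is an ordered list of rules, each an identified regex pattern
with a trained weight.  Training is not gradient-based: a rule's weight
is the signed sum, over every match it produces on every training
sequence, of (motif phenotype value × motif length) looked up in the
motif database — added when the motif's value is at or above the class
threshold, subtracted otherwise.  A peptide's predicted score is the
sum of the weights of the rules that match it (match presence, not
match count), and model fitness is the Pearson correlation between
predicted scores and true phenotypes, optionally under k-fold
cross-validation with per-fold database rebuilds.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import PeptideDataset
from .motifs import MotifDatabase, build_motif_db
from .regex_tree import MatchTimeoutError, RegexTree, match_all

logger = logging.getLogger(__name__)

MAX_RULES = 30


@dataclass
class Rule:
    """An identified regex with a trained weight.

    Either ``tree`` (the evolvable genotype) or ``pattern`` (a raw
    pattern string, e.g. loaded from a model file) must be provided.
    """

    id: int
    tree: RegexTree | None = None
    pattern: str | None = None
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.tree is None and self.pattern is None:
            raise ValueError("a rule needs a tree or a raw pattern")
        try:
            re.compile(self.pattern_str)
        except re.error as exc:
            raise ValueError(f"rule {self.id}: invalid pattern: {exc}") from exc

    @property
    def pattern_str(self) -> str:
        return self.tree.pattern if self.tree is not None else self.pattern

    def copy(self) -> "Rule":
        return Rule(
            self.id,
            self.tree.copy() if self.tree is not None else None,
            self.pattern,
            self.weight,
        )


@dataclass
class Model:
    """An ordered rule list — one individual / protein-function model."""

    rules: list[Rule] = field(default_factory=list)
    fitness: float | None = None
    validation_fitness: float | None = None
    max_rules: int = MAX_RULES

    def __post_init__(self) -> None:
        if not 1 <= len(self.rules) <= self.max_rules:
            raise ValueError(
                f"rule count must be in 1..{self.max_rules}, got {len(self.rules)}"
            )
        ids = [r.id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ValueError(f"rule ids must be unique, got {ids}")

    def __len__(self) -> int:
        return len(self.rules)

    def copy(self) -> "Model":
        return Model(
            [r.copy() for r in self.rules],
            self.fitness,
            self.validation_fitness,
            self.max_rules,
        )

    def reassign_ids(self) -> None:
        for i, rule in enumerate(self.rules):
            rule.id = i


def _safe_matches(pattern: str, sequence: str) -> list[str]:
    """Matches of ``pattern``; a timed-out scan counts as non-matching."""
    try:
        return match_all(pattern, sequence)
    except MatchTimeoutError:
        return []


def score_matches(matches: list[str], db: MotifDatabase) -> float:
    """Signed motif score of one sequence's matches against the database.

    Each matched substring with a database entry contributes
    ``±value × length``: positive when the motif value is at or above
    the threshold, negative below it.  Matches absent from the database
    (unseen, or longer than the largest window) contribute nothing.
    """
    total = 0.0
    for m in matches:
        rec = db.lookup(m)
        if rec is None:
            continue
        contribution = rec.cest_value * len(m)
        total += contribution if rec.cest_value >= db.threshold else -contribution
    return total


def train_rule_weight(
    rule: Rule, train: PeptideDataset, db: MotifDatabase
) -> float:
    """The rule's final weight: motif scores summed over all training
    sequences (see :func:`score_matches`)."""
    return sum(
        score_matches(_safe_matches(rule.pattern_str, seq), db)
        for seq in train.sequences
    )


def train_model_weights(
    model: Model, train: PeptideDataset, db: MotifDatabase
) -> Model:
    """Train every rule's weight in place (rules are independent, so the
    result does not depend on evaluation order); returns ``model``."""
    for rule in model.rules:
        rule.weight = train_rule_weight(rule, train, db)
    return model


def predict_score(model: Model, sequence: str) -> float:
    """Predicted score: sum of weights of the rules that match at least
    once in ``sequence`` (match presence gates the weight, not count)."""
    return sum(
        rule.weight
        for rule in model.rules
        if _safe_matches(rule.pattern_str, sequence)
    )


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r with a defined degenerate case: 0.0 when either vector
    has zero variance (an uninformative model is 'uncorrelated', not an
    error)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum()) * np.sqrt((yc**2).sum())
    if denom == 0.0:
        return 0.0
    return float((xc * yc).sum() / denom)


def pearson_fitness(model: Model, data: PeptideDataset) -> float:
    """Pearson correlation between the model's predicted scores and the
    true phenotypes of ``data`` (the evolutionary objective)."""
    if len(data) < 2:
        raise ValueError("need at least 2 records")
    scores = np.array([predict_score(model, s) for s in data.sequences])
    return pearson(scores, data.phenotypes)


def assign_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded balanced fold labels in ``0..k-1`` for ``n`` records."""
    if n < k:
        raise ValueError(f"need at least k={k} records, got {n}")
    labels = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
    return np.random.default_rng(seed).permutation(labels)


def kfold_fitness(
    model: Model,
    train: PeptideDataset,
    k: int = 6,
    threshold: float = 12.5,
    seed: int = 0,
) -> tuple[float, float]:
    """k-fold fitness of a model under full per-fold retraining.

    For each fold the motif database is rebuilt from the other k−1
    folds (no held-out phenotype leaks into any weight), rule weights
    are trained on those folds, and Pearson r is computed both on the
    training folds and on the held-out fold.  Returns
    ``(fitness, validation)``: the mean training-fold r (the
    evolutionary fitness) and the mean held-out r (an overfitting
    monitor).
    """
    folds = assign_folds(len(train), k, seed)
    y = train.phenotypes
    r_train, r_val = [], []
    for f in range(k):
        tr_idx = np.flatnonzero(folds != f)
        va_idx = np.flatnonzero(folds == f)
        tr = train.subset(tr_idx.tolist())
        db = build_motif_db(tr, threshold=threshold)
        trained = train_model_weights(model.copy(), tr, db)
        scores = np.array([predict_score(trained, s) for s in train.sequences])
        r_train.append(pearson(scores[tr_idx], y[tr_idx]))
        r_val.append(pearson(scores[va_idx], y[va_idx]))
    return float(np.mean(r_train)), float(np.mean(r_val))


def randomize_weights(
    model: Model,
    rng: np.random.Generator,
    p: float = 0.1,
    low: float = -10.0,
    high: float = 10.0,
) -> Model:
    """Random-weight control: each rule's weight is independently
    replaced by ``Uniform(low, high)`` with probability ``p``.  With
    ``p=1`` this (re)initializes every weight; the control mode of the
    evolutionary engine uses it in place of training."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if low >= high:
        raise ValueError(f"need low < high, got [{low}, {high}]")
    for rule in model.rules:
        if p == 1.0 or rng.random() < p:
            rule.weight = float(rng.uniform(low, high))
    return model


# ---------------------------------------------------------------------------
# model files
# ---------------------------------------------------------------------------


def save_model(model: Model, path: str | Path) -> None:
    """Write ``id,pattern,weight`` CSV; tree genotypes, when present, go
    to a ``<path>.trees.json`` side file so a round trip is lossless."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "pattern", "weight"])
        for rule in model.rules:
            writer.writerow([rule.id, rule.pattern_str, repr(rule.weight)])
    trees = {
        str(rule.id): json.loads(rule.tree.to_json())
        for rule in model.rules
        if rule.tree is not None
    }
    if trees:
        Path(f"{path}.trees.json").write_text(json.dumps(trees))


def load_model(path: str | Path) -> Model:
    """Load a rules-table CSV (``id,pattern,weight``), restoring tree
    genotypes from the side file when one exists."""
    path = Path(path)
    side = Path(f"{path}.trees.json")
    trees = json.loads(side.read_text()) if side.exists() else {}
    rules = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"id", "pattern", "weight"} <= set(
            reader.fieldnames
        ):
            raise ValueError(f"{path}: expected header id,pattern,weight")
        for row_no, row in enumerate(reader, start=2):
            try:
                tree = None
                if str(row["id"]) in trees:
                    tree = RegexTree.from_json(json.dumps(trees[str(row["id"])]))
                rules.append(
                    Rule(
                        int(row["id"]),
                        tree=tree,
                        pattern=row["pattern"] if tree is None else None,
                        weight=float(row["weight"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}: bad rule at line {row_no}: {exc}") from exc
    if not rules:
        raise ValueError(f"{path}: no rules found")
    # externally supplied models may be wider than the evolutionary cap
    return Model(rules, max_rules=max(MAX_RULES, len(rules)))
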