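"""Regular expressions encoded as depth-bounded binary trees.

A pattern genotype is a binary tree stored in heap layout: node ``i``
has children ``2i+1`` and ``2i+2``, unexpressed slots hold ``None``.
Internal nodes are operators (concatenation, alternation, ``+``,
``{n}``, bracket class, excluding bracket class, group), leaves hold one
or more amino-acid letters.  The depth bound (default 6) caps pattern
length so matching stays cheap, and the heap array for depth 6 has
2^6 − 1 = 63 slots.

Rendering conventions
---------------------
* concatenation: children rendered adjacently;
* alternation: ``(A|B)``;
* ``+`` / ``{n}``: the operand is parenthesized unless it is a single
  letter or a bracket class, which also prevents ``++``-style syntax
  errors from nested quantifiers;
* bracket classes: the unary bracket operator flattens its subtree — the
  distinct letters of every leaf below it, in first-appearance order,
  become the class members (``[PNYIQ]`` / ``[^PNYIQ]``); any operators
  inside the subtree are ignored at render time, and random generation
  avoids placing quantifiers under a bracket;
* group: ``(X)``.

The rendered patterns use only Perl-compatible syntax understood by the
standard :mod:`re` engine, which performs all matching.
"""

from __future__ import annotations

import functools
import json
import logging
import re
import time
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .datasets import AMINO_ACIDS

logger = logging.getLogger(__name__)

MAX_DEPTH = 6

CONCAT = "concat"
ALTERNATION = "alternation"
PLUS = "plus"
REPEAT = "repeat"
CHARCLASS = "charclass"
NEGATED_CHARCLASS = "negated_charclass"
GROUP = "group"

#: Operator → arity (Table of supported RE operators).
ARITY = {
    CONCAT: 2,
    ALTERNATION: 2,
    PLUS: 1,
    REPEAT: 1,
    CHARCLASS: 1,
    NEGATED_CHARCLASS: 1,
    GROUP: 1,
}
OPERATORS = tuple(ARITY)
#: Operators allowed beneath a bracket class during generation (the
#: bracket flattens its subtree to letters, so quantifiers there would
#: be dead weight).
BRACKET_SAFE_OPERATORS = (CONCAT, ALTERNATION, GROUP)
REPEAT_COUNT_RANGE = (2, 9)  # inclusive bounds for {n}

MUTATION_KINDS = ("replace_subtree", "exchange_node", "delete_subtree", "add_leaf_aa")


class TreeStructureError(ValueError):
    """Raised when a heap array does not encode a valid tree."""


class MatchTimeoutError(RuntimeError):
    """Raised when a single pattern scan exceeds its time budget."""


@dataclass(frozen=True)
class RegexNode:
    """One slot of the heap array: an operator or a leaf payload."""

    kind: str  # "operator" | "leaf"
    operator: str | None = None
    payload: str | None = None
    repeat_count: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "operator":
            if self.operator not in ARITY:
                raise ValueError(f"unknown operator {self.operator!r}")
            if self.operator == REPEAT and self.repeat_count is None:
                raise ValueError("repeat operator requires repeat_count")
        elif self.kind == "leaf":
            if not self.payload:
                raise ValueError("leaf payload must be non-empty")
            if any(c not in AMINO_ACIDS for c in self.payload):
                raise ValueError(f"leaf payload {self.payload!r} has non-AA letters")
        else:
            raise ValueError(f"kind must be 'operator' or 'leaf', got {self.kind!r}")

    @property
    def arity(self) -> int:
        return ARITY[self.operator] if self.kind == "operator" else 0


def leaf(payload: str) -> RegexNode:
    return RegexNode("leaf", payload=payload)


def op(operator: str, repeat_count: int | None = None) -> RegexNode:
    return RegexNode("operator", operator=operator, repeat_count=repeat_count)


def _level(i: int) -> int:
    """1-based depth level of heap index ``i`` (root is level 1)."""
    return int(np.log2(i + 1)) + 1


class RegexTree:
    """A validated heap-layout regex tree with a cached pattern string."""

    __slots__ = ("nodes", "max_depth", "_pattern")

    def __init__(self, nodes: list[RegexNode | None], max_depth: int = MAX_DEPTH):
        size = 2**max_depth - 1
        if len(nodes) > size:
            raise TreeStructureError(
                f"heap array of length {len(nodes)} exceeds depth-{max_depth} bound"
            )
        self.nodes: list[RegexNode | None] = list(nodes) + [None] * (size - len(nodes))
        self.max_depth = max_depth
        self._pattern: str | None = None
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        nodes = self.nodes
        if nodes[0] is None:
            raise TreeStructureError("root slot (index 0) is empty")
        size = len(nodes)
        reachable = set(self._subtree_indices(0))
        for i, node in enumerate(nodes):
            if node is None:
                continue
            if i not in reachable:
                raise TreeStructureError(f"orphan node at index {i}")
            l, r = 2 * i + 1, 2 * i + 2
            have = [c for c in (l, r) if c < size and nodes[c] is not None]
            if node.kind == "leaf":
                if have:
                    raise TreeStructureError(f"leaf at index {i} has children")
            else:
                want = [l, r][: node.arity]
                if any(c >= size for c in want):
                    raise TreeStructureError(
                        f"operator at index {i} exceeds the depth bound"
                    )
                if have != want:
                    raise TreeStructureError(
                        f"operator {node.operator} at index {i} expects children "
                        f"at {want}, found {have}"
                    )

    def _subtree_indices(self, i: int) -> Iterator[int]:
        if i >= len(self.nodes) or self.nodes[i] is None:
            return
        yield i
        yield from self._subtree_indices(2 * i + 1)
        yield from self._subtree_indices(2 * i + 2)

    def indices(self) -> list[int]:
        """Heap indices of all expressed nodes (preorder)."""
        return list(self._subtree_indices(0))

    def depth(self) -> int:
        """Tree depth: a single leaf has depth 1."""
        return max(_level(i) for i in self.indices())

    def copy(self) -> "RegexTree":
        return RegexTree(list(self.nodes), self.max_depth)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RegexTree) and self.nodes == other.nodes

    def __repr__(self) -> str:
        return f"RegexTree({self.pattern!r})"

    # -- rendering ---------------------------------------------------------

    @property
    def pattern(self) -> str:
        if self._pattern is None:
            self._pattern = self._render(0)
        return self._pattern

    def _leaf_letters(self, i: int) -> str:
        seen: dict[str, None] = {}
        for j in self._subtree_indices(i):
            node = self.nodes[j]
            if node.kind == "leaf":
                for c in node.payload:
                    seen.setdefault(c, None)
        return "".join(seen)

    def _render(self, i: int) -> str:
        node = self.nodes[i]
        l, r = 2 * i + 1, 2 * i + 2
        if node.kind == "leaf":
            return node.payload
        o = node.operator
        if o == CONCAT:
            return self._render(l) + self._render(r)
        if o == ALTERNATION:
            return f"({self._render(l)}|{self._render(r)})"
        if o == PLUS:
            return f"{self._quantifier_operand(l)}+"
        if o == REPEAT:
            return f"{self._quantifier_operand(l)}{{{node.repeat_count}}}"
        if o == CHARCLASS:
            return f"[{self._leaf_letters(l)}]"
        if o == NEGATED_CHARCLASS:
            return f"[^{self._leaf_letters(l)}]"
        if o == GROUP:
            return f"({self._render(l)})"
        raise AssertionError(o)

    def _quantifier_operand(self, i: int) -> str:
        operand = self._render(i)
        if len(operand) == 1 or _is_single_token(operand):
            return operand
        return f"({operand})"

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        def enc(n: RegexNode | None):
            if n is None:
                return None
            if n.kind == "leaf":
                return {"leaf": n.payload}
            d = {"op": n.operator}
            if n.repeat_count is not None:
                d["n"] = n.repeat_count
            return d

        return json.dumps(
            {"max_depth": self.max_depth, "nodes": [enc(n) for n in self.nodes],
             "pattern": self.pattern}
        )

    @classmethod
    def from_json(cls, text: str) -> "RegexTree":
        data = json.loads(text)

        def dec(d):
            if d is None:
                return None
            if "leaf" in d:
                return leaf(d["leaf"])
            return op(d["op"], d.get("n"))

        return cls([dec(d) for d in data["nodes"]], data.get("max_depth", MAX_DEPTH))


def _is_single_token(s: str) -> bool:
    """True for one letter, one bracket class, or one fully parenthesized
    group — operands that can take a quantifier without extra parens."""
    if len(s) == 1:
        return True
    if s.startswith("[") and s.endswith("]") and "]" not in s[1:-1]:
        return True
    if s.startswith("(") and s.endswith(")"):
        depth = 0
        for k, c in enumerate(s):
            depth += c == "("
            depth -= c == ")"
            if depth == 0 and k < len(s) - 1:
                return False
        return True
    return False


def tree_depth(tree: RegexTree) -> int:
    return tree.depth()


def to_pattern(tree: RegexTree) -> str:
    return tree.pattern


# ---------------------------------------------------------------------------
# random generation
# ---------------------------------------------------------------------------

#: Probability that ``grow`` generation terminates a branch early with a
#: leaf (above the forced-leaf deepest level).
GROW_LEAF_PROBABILITY = 0.45

#: Leaf payload length distribution at generation time: short contiguous
#: motifs are first-class genotypes (evolved models in this problem
#: family typically mix plain motifs with composite expressions).
_LEAF_LENGTHS = (1, 2, 3)
_LEAF_LENGTH_WEIGHTS = (0.5, 0.3, 0.2)

#: Operator sampling weights at generation time.  Concatenation is
#: favoured (it composes motifs); the excluding bracket is down-weighted
#: because it matches almost any residue and mostly produces
#: uninformative always-on rules.
_OPERATOR_WEIGHTS = {
    CONCAT: 3.0,
    ALTERNATION: 1.5,
    PLUS: 1.0,
    REPEAT: 0.5,
    CHARCLASS: 1.0,
    NEGATED_CHARCLASS: 0.5,
    GROUP: 0.5,
}


def generate_random_tree(
    max_depth: int,
    method: str,
    rng: np.random.Generator,
    *,
    depth_bound: int = MAX_DEPTH,
) -> RegexTree:
    """Generate a random tree of depth ≤ ``max_depth``.

    ``full`` places operators on every level above the deepest, ``grow``
    may terminate branches early with leaves.  ``depth_bound`` sets the
    heap-array capacity (callers grafting subtrees pass the remaining
    room); population-level ramped half-and-half is the engine's job.
    """
    if max_depth < 1:
        raise ValueError(f"max_depth must be >= 1, got {max_depth}")
    if method not in ("full", "grow"):
        raise ValueError(f"method must be 'full' or 'grow', got {method!r}")
    nodes: list[RegexNode | None] = [None] * (2**depth_bound - 1)
    _fill(nodes, 0, max_depth, method, rng, in_bracket=False)
    return RegexTree(nodes, depth_bound)


def _random_leaf(rng: np.random.Generator) -> RegexNode:
    length = _LEAF_LENGTHS[
        rng.choice(len(_LEAF_LENGTHS), p=_LEAF_LENGTH_WEIGHTS)
    ]
    return leaf(
        "".join(AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))] for _ in range(length))
    )


def _random_repeat_count(rng: np.random.Generator) -> int:
    lo, hi = REPEAT_COUNT_RANGE
    return int(rng.integers(lo, hi + 1))


def _fill(
    nodes: list[RegexNode | None],
    i: int,
    remaining: int,
    method: str,
    rng: np.random.Generator,
    in_bracket: bool,
) -> None:
    make_leaf = remaining <= 1 or (
        method == "grow" and rng.random() < GROW_LEAF_PROBABILITY
    )
    if make_leaf:
        nodes[i] = _random_leaf(rng)
        return
    pool = BRACKET_SAFE_OPERATORS if in_bracket else OPERATORS
    weights = np.array([_OPERATOR_WEIGHTS[o] for o in pool])
    o = pool[rng.choice(len(pool), p=weights / weights.sum())]
    nodes[i] = op(o, _random_repeat_count(rng) if o == REPEAT else None)
    child_bracket = in_bracket or o in (CHARCLASS, NEGATED_CHARCLASS)
    for c in range(ARITY[o]):
        _fill(nodes, 2 * i + 1 + c, remaining - 1, method, rng, child_bracket)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

#: Wall-clock budget for a single pattern scan, seconds.  Subjects here
#: are short peptides whose scans take microseconds, so the budget is
#: generous enough that only genuine pathology (or nothing) trips it —
#: a spurious trip under system load would make evaluation
#: nondeterministic.
MATCH_TIME_BUDGET = 2.0


@functools.lru_cache(maxsize=65536)
def _compile(pattern: str) -> re.Pattern:
    return re.compile(pattern)


def match_all(
    pattern: str, sequence: str, time_budget: float = MATCH_TIME_BUDGET
) -> list[str]:
    """Non-overlapping leftmost matches of ``pattern`` in ``sequence``.

    Standard regex scan semantics; the returned strings are the full
    matched substrings.  Empty matches cannot arise because leaves are
    non-empty and all quantifiers require at least one repetition.
    A scan running past ``time_budget`` raises
    :class:`MatchTimeoutError`; callers treating the pattern as a model
    rule score it as non-matching instead of aborting a whole run.
    """
    try:
        compiled = _compile(pattern)
    except re.error as exc:
        raise ValueError(f"invalid pattern {pattern!r}: {exc}") from exc
    t0 = time.perf_counter()
    out = [m.group(0) for m in compiled.finditer(sequence)]
    if time.perf_counter() - t0 > time_budget:
        logger.warning("pattern %r exceeded the match time budget", pattern)
        raise MatchTimeoutError(pattern)
    return out


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------


def mutate_tree(tree: RegexTree, kind: str, rng: np.random.Generator) -> RegexTree:
    """Apply one structural mutation; always returns a *new* valid tree.

    ``replace_subtree``
        a uniformly chosen subtree is replaced by a freshly grown one
        whose depth respects the global bound;
    ``exchange_node``
        one node's value is swapped within its arity class
        (concatenation↔alternation, bracket↔excluding bracket,
        ``+``↔``{n}``, a leaf letter → a different random letter,
        an ``{n}`` count → a different count);
    ``delete_subtree``
        a non-root subtree is removed; the sibling branch is promoted
        (for a unary parent the parent chain collapses with it);
    ``add_leaf_aa``
        1–4 random letters are appended to a random leaf's payload.
    """
    if kind == "replace_subtree":
        return _mutate_replace(tree, rng)
    if kind == "exchange_node":
        return _mutate_exchange(tree, rng)
    if kind == "delete_subtree":
        return _mutate_delete(tree, rng)
    if kind == "add_leaf_aa":
        return _mutate_add_leaf(tree, rng)
    raise ValueError(f"unknown mutation kind {kind!r}")


def _clear_subtree(nodes: list[RegexNode | None], i: int) -> None:
    if i >= len(nodes) or nodes[i] is None:
        return
    nodes[i] = None
    _clear_subtree(nodes, 2 * i + 1)
    _clear_subtree(nodes, 2 * i + 2)


def _graft(
    dst: list[RegexNode | None],
    dst_i: int,
    src: list[RegexNode | None],
    src_i: int,
) -> None:
    """Copy the subtree rooted at ``src[src_i]`` to position ``dst_i``."""
    if src_i >= len(src) or src[src_i] is None:
        return
    dst[dst_i] = src[src_i]
    for c in range(2):
        _graft(dst, 2 * dst_i + 1 + c, src, 2 * src_i + 1 + c)


def _in_bracket_subtree(tree: RegexTree, i: int) -> bool:
    while i > 0:
        i = (i - 1) // 2
        node = tree.nodes[i]
        if node.operator in (CHARCLASS, NEGATED_CHARCLASS):
            return True
    return False


def _mutate_replace(tree: RegexTree, rng: np.random.Generator) -> RegexTree:
    idx = tree.indices()
    target = idx[rng.integers(len(idx))]
    room = tree.max_depth - _level(target) + 1
    fresh = generate_random_tree(
        int(rng.integers(1, room + 1)), "grow", rng, depth_bound=tree.max_depth
    )
    if _in_bracket_subtree(tree, target):
        # keep quantifiers out of bracket subtrees (render-time dead weight)
        fresh = generate_random_tree(1, "grow", rng, depth_bound=tree.max_depth)
    nodes = list(tree.nodes)
    _clear_subtree(nodes, target)
    _graft(nodes, target, fresh.nodes, 0)
    return RegexTree(nodes, tree.max_depth)


_EXCHANGE_PARTNER = {
    CONCAT: ALTERNATION,
    ALTERNATION: CONCAT,
    CHARCLASS: NEGATED_CHARCLASS,
    NEGATED_CHARCLASS: CHARCLASS,
    PLUS: REPEAT,
}


def _mutate_exchange(tree: RegexTree, rng: np.random.Generator) -> RegexTree:
    eligible = [
        i
        for i in tree.indices()
        if tree.nodes[i].kind == "leaf" or tree.nodes[i].operator != GROUP
    ]
    if not eligible:  # a bare group chain; nothing to swap
        logger.debug("exchange_node: no eligible node, returning copy")
        return tree.copy()
    i = eligible[rng.integers(len(eligible))]
    node = tree.nodes[i]
    nodes = list(tree.nodes)
    if node.kind == "leaf":
        pos = int(rng.integers(len(node.payload)))
        alternatives = [c for c in AMINO_ACIDS if c != node.payload[pos]]
        aa = alternatives[rng.integers(len(alternatives))]
        nodes[i] = leaf(node.payload[:pos] + aa + node.payload[pos + 1 :])
    elif node.operator == REPEAT:
        if rng.random() < 0.5:
            nodes[i] = op(PLUS)
        else:
            choices = [
                n
                for n in range(REPEAT_COUNT_RANGE[0], REPEAT_COUNT_RANGE[1] + 1)
                if n != node.repeat_count
            ]
            nodes[i] = op(REPEAT, choices[rng.integers(len(choices))])
    elif node.operator == PLUS:
        nodes[i] = op(REPEAT, _random_repeat_count(rng))
    else:
        nodes[i] = op(_EXCHANGE_PARTNER[node.operator])
    return RegexTree(nodes, tree.max_depth)


def _mutate_delete(tree: RegexTree, rng: np.random.Generator) -> RegexTree:
    candidates = [i for i in tree.indices() if i != 0]
    if not candidates:
        logger.debug("delete_subtree on a single-node tree is a no-op")
        return tree.copy()
    target = candidates[rng.integers(len(candidates))]
    # climb unary chains: deleting the only child of a unary operator
    # deletes the operator too
    while True:
        parent = (target - 1) // 2
        if tree.nodes[parent].arity == 2:
            break
        if parent == 0:
            logger.debug("delete_subtree would erase the root; no-op")
            return tree.copy()
        target = parent
    parent = (target - 1) // 2
    sibling = 2 * parent + 1 if target == 2 * parent + 2 else 2 * parent + 2
    nodes = list(tree.nodes)
    _clear_subtree(nodes, parent)
    _graft(nodes, parent, tree.nodes, sibling)
    return RegexTree(nodes, tree.max_depth)


def _mutate_add_leaf(tree: RegexTree, rng: np.random.Generator) -> RegexTree:
    leaves = [i for i in tree.indices() if tree.nodes[i].kind == "leaf"]
    i = leaves[rng.integers(len(leaves))]
    extra = "".join(
        AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
        for _ in range(int(rng.integers(1, 5)))
    )
    nodes = list(tree.nodes)
    nodes[i] = leaf(tree.nodes[i].payload + extra)
    return RegexTree(nodes, tree.max_depth)
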