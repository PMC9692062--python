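"""Slot-ordering search: baselines, constrained sampling, hill climbing.

The space of orderings is the product of per-side permutations of the
affix slots (a slot never changes side).  Baseline families follow the
comparison design: uniform random orderings, random orderings constrained
to satisfy typological ordering universals (e.g. number before case,
counting distance from the root), the reversed attested ordering, and
orderings optimized to minimize the tradeoff-curve AUC by steepest-descent
hill climbing with random restarts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Callable, Sequence

import numpy as np

from .corpus_io import Corpus
from .infotheory import auc, estimate_entropy_ladder, it_profile, tradeoff_curve
from .ordering import PREFIX, SUFFIX, OrderingGrammar, SlotSchema, linearize

__all__ = [
    "UniversalConstraints",
    "sample_random_grammar",
    "sample_universal_grammar",
    "enumerate_grammars",
    "hill_climb",
    "HillClimbResult",
    "auc_objective",
    "n_grammars",
]

DEFAULT_ENUMERATION_CAP = 10_000
_REJECTION_BUDGET = 10_000


@dataclass(frozen=True)
class UniversalConstraints:
    """Precedence pairs over universal classes, as distance from the root.

    ``(closer, farther)`` means every slot of class *closer* sits strictly
    closer to the root than every slot of class *farther*, comparing
    distance-from-root ranks within and across sides.  The induced relation
    must be a strict partial order (acyclic).
    """

    precedence: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "precedence", tuple((a, b) for a, b in self.precedence)
        )
        graph: dict[str, set[str]] = {}
        for closer, farther in self.precedence:
            graph.setdefault(farther, set()).add(closer)
        try:
            tuple(TopologicalSorter(graph).static_order())
        except CycleError as exc:
            raise ValueError(f"constraint classes form a cycle: {exc}") from exc

    @classmethod
    def from_chain(cls, chain: Sequence[str]) -> "UniversalConstraints":
        """All pairwise constraints implied by an ordered class list."""
        return cls(tuple(itertools.combinations(chain, 2)))

    def satisfied_by(self, grammar: OrderingGrammar, schema: SlotSchema) -> bool:
        for closer, farther in self.precedence:
            near = [
                grammar.ranks[s.slot_id]
                for s in schema.slots
                if s.universal_class == closer
            ]
            far = [
                grammar.ranks[s.slot_id]
                for s in schema.slots
                if s.universal_class == farther
            ]
            if near and far and max(near) >= min(far):
                return False
        return True


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def n_grammars(schema: SlotSchema) -> int:
    """Size of the ordering space: product of per-side factorials."""
    return math.factorial(len(schema.side_slots(PREFIX))) * math.factorial(
        len(schema.side_slots(SUFFIX))
    )


def _grammar_from_side_orders(
    schema: SlotSchema, orders: dict[str, Sequence[str]]
) -> OrderingGrammar:
    ranks: dict[str, int] = {}
    for side, order in orders.items():
        for r, sid in enumerate(order, start=1):
            ranks[sid] = r
    return OrderingGrammar(ranks)


def sample_random_grammar(
    schema: SlotSchema, seed: int | np.random.Generator
) -> OrderingGrammar:
    """One ordering drawn uniformly from the per-side permutation space."""
    rng = _as_rng(seed)
    orders = {}
    for side in (PREFIX, SUFFIX):
        ids = [s.slot_id for s in schema.side_slots(side)]
        orders[side] = [ids[i] for i in rng.permutation(len(ids))]
    return _grammar_from_side_orders(schema, orders)


def sample_universal_grammar(
    schema: SlotSchema,
    constraints: UniversalConstraints,
    seed: int | np.random.Generator,
    rejection_budget: int = _REJECTION_BUDGET,
) -> OrderingGrammar:
    """Uniform sample over orderings satisfying *constraints*.

    Rejection sampling from the uniform sampler; if the budget is exhausted
    the admissible set is enumerated exactly (and an empty set raises).
    """
    rng = _as_rng(seed)
    for _ in range(rejection_budget):
        g = sample_random_grammar(schema, rng)
        if constraints.satisfied_by(g, schema):
            return g
    admissible = [
        g
        for g in enumerate_grammars(schema, cap=DEFAULT_ENUMERATION_CAP)
        if constraints.satisfied_by(g, schema)
    ]
    if not admissible:
        raise ValueError("constraints are unsatisfiable on this schema")
    return admissible[int(rng.integers(len(admissible)))]


def enumerate_grammars(
    schema: SlotSchema, cap: int = DEFAULT_ENUMERATION_CAP
) -> list[OrderingGrammar]:
    """All orderings, in deterministic lexicographic order of the side
    permutations (schema slot order defines the base sequence)."""
    total = n_grammars(schema)
    if total > cap:
        raise ValueError(
            f"{total} grammars exceed cap {cap}; use sampling instead"
        )
    pre = [s.slot_id for s in schema.side_slots(PREFIX)]
    suf = [s.slot_id for s in schema.side_slots(SUFFIX)]
    out = []
    for p in itertools.permutations(pre):
        for q in itertools.permutations(suf):
            out.append(_grammar_from_side_orders(schema, {PREFIX: p, SUFFIX: q}))
    return out


# ---------------------------------------------------------------------------
# hill climbing


@dataclass
class HillClimbResult:
    best_grammar: OrderingGrammar
    best_objective: float
    #: per restart, the strictly decreasing objective values along the path
    trace: list[list[float]] = field(default_factory=list)
    n_evaluations: int = 0


def auc_objective(
    corpus: Corpus,
    t_max: int | None = None,
    estimator: str = "plugin",
    **estimator_kwargs,
) -> Callable[[OrderingGrammar], float]:
    """The default search objective: tradeoff-curve AUC of the linearized
    corpus under a candidate grammar (lower = more information-local).

    The corpus is collapsed to weighted types once, so each evaluation
    linearizes distinct forms only.
    """
    def canonical(w) -> tuple:
        return (
            w.root,
            tuple(sorted((a.side, a.slot_id, a.value_label) for a in w.affixes)),
        )

    groups: dict[tuple, list] = {}
    for w in corpus.words:
        groups.setdefault(canonical(w), [w, 0])[1] += 1
    types = [tuple(groups[k]) for k in sorted(groups)]
    if t_max is None:
        t_max = max(1 + len(w.affixes) for w, _ in types) + 1

    def objective(grammar: OrderingGrammar) -> float:
        seqs = [linearize(w, grammar) for w, _ in types]
        weights = [c for _, c in types]
        ladder = estimate_entropy_ladder(
            seqs, t_max, estimator, weights=weights if estimator == "plugin" else None,
            **estimator_kwargs,
        )
        return auc(tradeoff_curve(it_profile(ladder, estimator)))

    return objective


def _neighbors(grammar: OrderingGrammar, schema: SlotSchema):
    """Single-slot relocations within a side, deterministic order."""
    for side in (PREFIX, SUFFIX):
        order = list(grammar.side_order(schema, side))
        for i in range(len(order)):
            for j in range(len(order)):
                if i == j:
                    continue
                moved = order.copy()
                sid = moved.pop(i)
                moved.insert(j, sid)
                yield _grammar_from_side_orders(
                    schema,
                    {
                        side: moved,
                        _other(side): grammar.side_order(schema, _other(side)),
                    },
                )


def _other(side: str) -> str:
    return SUFFIX if side == PREFIX else PREFIX


def hill_climb(
    corpus: Corpus,
    schema: SlotSchema,
    objective: Callable[[OrderingGrammar], float] | None = None,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 10,
) -> HillClimbResult:
    """Steepest-descent search for the minimum-objective ordering.

    Each restart starts from a uniform random grammar and repeatedly moves
    to the strictly best single-slot relocation until none improves.  Ties
    (among equally good neighbors, and among restarts) break toward the
    lexicographically smallest rank vector, making the whole search
    bit-reproducible given the seed.  Objective values are memoized per
    grammar, so repeated visits cost nothing.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if objective is None:
        objective = auc_objective(corpus, estimator="plugin")
    rng = _as_rng(seed)
    memo: dict[tuple[int, ...], float] = {}

    def evaluate(g: OrderingGrammar) -> float:
        key = g.rank_vector(schema)
        if key not in memo:
            value = objective(g)
            if not math.isfinite(value):
                raise ValueError(
                    f"objective returned non-finite value {value!r} for "
                    f"grammar with ranks {dict(g.ranks)!r}"
                )
            memo[key] = value
        return memo[key]

    best: tuple[float, tuple[int, ...], OrderingGrammar] | None = None
    traces: list[list[float]] = []
    for _ in range(n_restarts):
        g = sample_random_grammar(schema, rng)
        value = evaluate(g)
        path = [value]
        while True:
            candidates = [
                (evaluate(nb), nb.rank_vector(schema), nb)
                for nb in _neighbors(g, schema)
            ]
            if not candidates:
                break
            candidates.sort(key=lambda c: (c[0], c[1]))
            nb_value, _, nb = candidates[0]
            if nb_value < value:
                g, value = nb, nb_value
                path.append(value)
            else:
                break
        traces.append(path)
        key = (value, g.rank_vector(schema))
        if best is None or key < (best[0], best[1]):
            best = (value, g.rank_vector(schema), g)
    assert best is not None
    return HillClimbResult(
        best_grammar=best[2],
        best_objective=best[0],
        trace=traces,
        n_evaluations=len(memo),
    )
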