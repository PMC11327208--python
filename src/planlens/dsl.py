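"""Predicate Domain Specific Language.

Predicates are boolean feature detectors on (belief state, planning
operation) pairs — the vocabulary from which strategy descriptions are
built.  The grammar closes a hand-made base inventory under negation, the
second-order combinators ``among`` (a condition holds among a pool of
nodes) and ``all`` (every node satisfying one condition satisfies another),
and bounded conjunction/disjunction composition.  The full closure for the
default 12-node environment exceeds 14,000 distinct predicates; the
imitation-learning search operates on a curated sub-vocabulary
(:func:`default_vocabulary`) for tractability.

Conventions: predicates evaluate on ``(belief, action, config)`` where
``action`` may be :data:`~planlens.env.TERM`; evaluation is pure, and a
predicate that references a node class absent from the layout evaluates to
False rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np

from .env import TERM, BeliefState, EnvConfig, best_path

PredicateFn = Callable[[BeliefState, int, EnvConfig], bool]


class GrammarError(ValueError):
    """Raised when the grammar closure exceeds its configured hard cap."""


@dataclass(frozen=True, eq=False)
class Predicate:
    """A named boolean feature detector on (belief, operation) pairs."""

    name: str
    fn: PredicateFn
    #: "first_order" | "second_order" | "combinator"
    arity: str = "first_order"
    #: state-level predicates ignore the operation argument; only they are
    #: eligible as UNTIL/UNLESS conditions in procedural formulas.
    state_level: bool = False

    def __call__(self, belief: BeliefState, action: int, config: EnvConfig) -> bool:
        return bool(self.fn(belief, action, config))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Predicate) and other.name == self.name

    def __hash__(self) -> int:
        return hash(self.name)

    def __repr__(self) -> str:
        return f"Predicate({self.name!r})"


def negate(p: Predicate) -> Predicate:
    """Logical negation; ``not(not(p))`` canonicalizes back to ``p``'s name."""
    if p.name.startswith("not(") and p.name.endswith(")"):
        inner = p.name[4:-1]
        return Predicate(inner, lambda b, a, c, _p=p: not _p.fn(b, a, c),
                         arity="combinator", state_level=p.state_level)
    return Predicate(f"not({p.name})", lambda b, a, c, _p=p: not _p.fn(b, a, c),
                     arity="combinator", state_level=p.state_level)


def conjoin(a: Predicate, b: Predicate) -> Predicate:
    names = sorted([a.name, b.name])
    return Predicate(
        f"({names[0]} and {names[1]})",
        lambda bl, ac, cf, _a=a, _b=b: _a.fn(bl, ac, cf) and _b.fn(bl, ac, cf),
        arity="combinator",
        state_level=a.state_level and b.state_level,
    )


def disjoin(a: Predicate, b: Predicate) -> Predicate:
    names = sorted([a.name, b.name])
    return Predicate(
        f"({names[0]} or {names[1]})",
        lambda bl, ac, cf, _a=a, _b=b: _a.fn(bl, ac, cf) or _b.fn(bl, ac, cf),
        arity="combinator",
        state_level=a.state_level and b.state_level,
    )


# ---------------------------------------------------------------------------
# node-level conditions and node pools (arguments of among/all)
# ---------------------------------------------------------------------------

NodeConditionFn = Callable[[int, BeliefState, EnvConfig], bool]
NodePoolFn = Callable[[BeliefState, EnvConfig], Tuple[int, ...]]


@dataclass(frozen=True, eq=False)
class NodeCondition:
    name: str
    fn: NodeConditionFn

    def __eq__(self, other: object) -> bool:
        return isinstance(other, NodeCondition) and other.name == self.name

    def __hash__(self) -> int:
        return hash(self.name)


@dataclass(frozen=True, eq=False)
class NodePool:
    name: str
    fn: NodePoolFn

    def __eq__(self, other: object) -> bool:
        return isinstance(other, NodePool) and other.name == self.name

    def __hash__(self) -> int:
        return hash(self.name)


def negate_condition(c: NodeCondition) -> NodeCondition:
    return NodeCondition(f"not({c.name})", lambda n, b, cf, _c=c: not _c.fn(n, b, cf))


def conjoin_conditions(a: NodeCondition, b: NodeCondition) -> NodeCondition:
    names = sorted([a.name, b.name])
    return NodeCondition(
        f"({names[0]} and {names[1]})",
        lambda n, bl, cf, _a=a, _b=b: _a.fn(n, bl, cf) and _b.fn(n, bl, cf),
    )


def among(cond: NodeCondition, pool: NodePool) -> Predicate:
    """True iff some node in ``pool`` satisfies ``cond`` (state-level)."""

    def fn(belief: BeliefState, action: int, config: EnvConfig,
           _c=cond, _p=pool) -> bool:
        return any(_c.fn(n, belief, config) for n in _p.fn(belief, config))

    return Predicate(f"among({cond.name}, {pool.name})", fn,
                     arity="second_order", state_level=True)


def all_nodes_such_that(phi: NodeCondition, psi: NodeCondition) -> Predicate:
    """True iff every node satisfying ``phi`` also satisfies ``psi``.

    Vacuously true when no node satisfies ``phi``.
    """

    def fn(belief: BeliefState, action: int, config: EnvConfig,
           _f=phi, _g=psi) -> bool:
        return all(
            _g.fn(n, belief, config)
            for n in config.nodes
            if _f.fn(n, belief, config)
        )

    return Predicate(f"all({phi.name}, {psi.name})", fn,
                     arity="second_order", state_level=True)


# ---------------------------------------------------------------------------
# base inventory
# ---------------------------------------------------------------------------

def _sibling_of_previous(n: int, b: BeliefState, c: EnvConfig) -> bool:
    prev = b.last_click
    return prev is not None and n in c.siblings.get(prev, ())


def _same_branch_as_previous(n: int, b: BeliefState, c: EnvConfig) -> bool:
    prev = b.last_click
    return prev is not None and c.branch_of.get(n) == c.branch_of.get(prev)


def base_node_conditions(config: EnvConfig) -> List[NodeCondition]:
    conds = [
        NodeCondition("node_observed", lambda n, b, c: n in b.observed),
        NodeCondition("node_positive",
                      lambda n, b, c: b.observed.get(n, 0) > 0 and n in b.observed),
        NodeCondition("node_negative",
                      lambda n, b, c: n in b.observed and b.observed[n] < 0),
        NodeCondition("node_is_max_valued",
                      lambda n, b, c: b.observed.get(n) == c.max_reward),
        NodeCondition("node_is_leaf", lambda n, b, c: n in c.leaves),
        NodeCondition("node_is_root", lambda n, b, c: n in c.roots),
        NodeCondition("node_parent_observed",
                      lambda n, b, c: c.parent.get(n) in b.observed),
        NodeCondition("node_child_observed",
                      lambda n, b, c: any(k in b.observed
                                          for k in c.children.get(n, ()))),
        NodeCondition("node_on_best_path",
                      lambda n, b, c: n in best_path(b, c)),
        NodeCondition("node_sibling_of_previous", _sibling_of_previous),
        NodeCondition("node_same_branch_as_previous", _same_branch_as_previous),
    ]
    for d in sorted(set(config.depth.values())):
        conds.append(NodeCondition(
            f"node_depth_is_{d}", lambda n, b, c, _d=d: c.depth.get(n) == _d))
    return conds


def base_pools(config: EnvConfig) -> List[NodePool]:
    return [
        NodePool("all_nodes", lambda b, c: c.nodes),
        NodePool("leaves", lambda b, c: c.leaves),
        NodePool("roots", lambda b, c: c.roots),
        NodePool("unobserved_nodes",
                 lambda b, c: tuple(n for n in c.nodes if n not in b.observed)),
        NodePool("observed_nodes", lambda b, c: b.clicks),
        NodePool("branch_of_previous",
                 lambda b, c: tuple(n for n in c.nodes
                                    if b.last_click is not None
                                    and c.branch_of[n] == c.branch_of[b.last_click])),
    ]


def base_predicates(config: EnvConfig) -> List[Predicate]:
    """The named first-order inventory (action-level and state-level)."""

    def click(fn: Callable[[BeliefState, int, EnvConfig], bool]) -> PredicateFn:
        # action-level predicates are False on TERM
        return lambda b, a, c: a != TERM and fn(b, a, c)

    preds = [
        Predicate("is_observed", click(lambda b, a, c: a in b.observed)),
        Predicate("is_leaf", click(lambda b, a, c: a in c.leaves)),
        Predicate("is_root", click(lambda b, a, c: a in c.roots)),
        Predicate("is_term", lambda b, a, c: a == TERM),
        Predicate("is_previous_observed_sibling",
                  click(lambda b, a, c: _sibling_of_previous(a, b, c))),
        Predicate("is_previous_observed_parent",
                  click(lambda b, a, c: b.last_click is not None
                        and c.parent.get(a) == b.last_click)),
        Predicate("is_same_branch_as_previous",
                  click(lambda b, a, c: _same_branch_as_previous(a, b, c))),
        Predicate("has_parent_observed",
                  click(lambda b, a, c: c.parent.get(a) in b.observed)),
        Predicate("has_child_observed",
                  click(lambda b, a, c: any(k in b.observed
                                            for k in c.children.get(a, ())))),
        Predicate("is_on_best_path",
                  click(lambda b, a, c: a in best_path(b, c))),
    ]
    for d in sorted(set(config.depth.values())):
        preds.append(Predicate(
            f"depth_is_{d}", click(lambda b, a, c, _d=d: c.depth.get(a) == _d)))

    state = [
        Predicate("all_roots_observed",
                  lambda b, a, c: all(r in b.observed for r in c.roots),
                  state_level=True),
        Predicate("all_leaves_observed",
                  lambda b, a, c: all(l in b.observed for l in c.leaves),
                  state_level=True),
        Predicate("all_nodes_observed",
                  lambda b, a, c: len(b.observed) == c.n_nodes,
                  state_level=True),
        Predicate("is_max_observed",
                  lambda b, a, c: c.max_reward in b.observed.values(),
                  state_level=True),
        Predicate("is_positive_observed",
                  lambda b, a, c: any(v > 0 for v in b.observed.values()),
                  state_level=True),
        Predicate("is_previous_observed_max",
                  lambda b, a, c: b.last_value == c.max_reward,
                  state_level=True),
        Predicate("is_previous_observed_positive",
                  lambda b, a, c: b.last_value is not None and b.last_value > 0,
                  state_level=True),
        Predicate("is_previous_observed_leaf",
                  lambda b, a, c: b.last_click in c.leaves,
                  state_level=True),
        Predicate("is_previous_observed_root",
                  lambda b, a, c: b.last_click in c.roots,
                  state_level=True),
        Predicate("no_observations",
                  lambda b, a, c: len(b.observed) == 0,
                  state_level=True),
    ]
    return preds + state


TRUE_PREDICATE = Predicate("True", lambda b, a, c: True, state_level=True)


def evaluate(predicate: Predicate, belief: BeliefState, op: int,
             config: EnvConfig) -> bool:
    """Deterministic truth value of ``predicate`` on one (belief, op) pair."""
    return bool(predicate.fn(belief, op, config))


# ---------------------------------------------------------------------------
# grammar and enumeration
# ---------------------------------------------------------------------------

@dataclass
class PredicateGrammar:
    """Closure rules for generating the full DSL.

    The closure comprises: the base inventory and its negations;
    ``among(cond, pool)`` for every node-condition (base, negated, and
    pairwise conjunctions of base conditions) and pool, plus negations;
    ``all(phi, psi)`` for base conditions ``phi`` against the same
    condition closure, plus negations; pairwise conjunctions of base
    predicates; and pairwise disjunctions of state-level base predicates
    (the shapes the procedural-formula extraction needs).
    """

    base: List[Predicate]
    node_conditions: List[NodeCondition]
    pools: List[NodePool]
    max_condition_conjuncts: int = 2
    hard_cap: int = 500_000

    @classmethod
    def default(cls, config: EnvConfig) -> "PredicateGrammar":
        return cls(
            base=base_predicates(config),
            node_conditions=base_node_conditions(config),
            pools=base_pools(config),
        )


def _condition_closure(grammar: PredicateGrammar) -> List[NodeCondition]:
    base = list(grammar.node_conditions)
    signed = base + [negate_condition(c) for c in base]
    out = list(signed)
    if grammar.max_condition_conjuncts >= 2:
        for i in range(len(signed)):
            for j in range(i + 1, len(signed)):
                a, b = signed[i], signed[j]
                # skip contradictions c and not(c)
                if a.name == f"not({b.name})" or b.name == f"not({a.name})":
                    continue
                out.append(conjoin_conditions(a, b))
    return out


def enumerate_predicates(grammar: PredicateGrammar) -> List[Predicate]:
    """Generate the full, duplicate-free, deterministically ordered closure.

    Raises :class:`GrammarError` if the closure would exceed the hard cap.
    """
    seen: Dict[str, Predicate] = {}

    def add(p: Predicate) -> None:
        if p.name not in seen:
            if len(seen) >= grammar.hard_cap:
                raise GrammarError(
                    f"DSL closure exceeds hard cap {grammar.hard_cap}; "
                    "restrict the grammar (fewer pools/conditions or "
                    "max_condition_conjuncts=1)"
                )
            seen[p.name] = p

    signed_base = list(grammar.base) + [negate(p) for p in grammar.base]
    for p in signed_base:
        add(p)

    conditions = _condition_closure(grammar)
    signed_conditions = conditions  # already includes negations of base
    base_signed_conds = (grammar.node_conditions
                         + [negate_condition(c) for c in grammar.node_conditions])

    for cond in signed_conditions:
        for pool in grammar.pools:
            p = among(cond, pool)
            add(p)
            add(negate(p))

    for phi in base_signed_conds:
        for psi in signed_conditions:
            if phi.name == psi.name:
                continue
            p = all_nodes_such_that(phi, psi)
            add(p)
            add(negate(p))

    # bounded composition over the signed base inventory
    for i in range(len(signed_base)):
        for j in range(i + 1, len(signed_base)):
            a, b = signed_base[i], signed_base[j]
            if a.name == f"not({b.name})" or b.name == f"not({a.name})":
                continue
            add(conjoin(a, b))

    state_signed = [p for p in signed_base if p.state_level]
    for i in range(len(state_signed)):
        for j in range(i + 1, len(state_signed)):
            a, b = state_signed[i], state_signed[j]
            if a.name == f"not({b.name})" or b.name == f"not({a.name})":
                continue
            add(disjoin(a, b))

    return list(seen.values())


def default_vocabulary(config: EnvConfig) -> List[Predicate]:
    """The sub-vocabulary the DNF search uses by default.

    The full closure is far too large to evaluate on every demonstration;
    the base inventory (with negations handled inside the search) already
    spans the concepts the benchmark strategies are phrased in.
    """
    return base_predicates(config)


def export_manifest(predicates: Sequence[Predicate], path) -> None:
    """Write the predicate list as a text manifest, one name per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in predicates:
            fh.write(p.name + "\n")


def valuation_matrix(
    pairs: Sequence[Tuple[BeliefState, int]],
    predicates: Sequence[Predicate],
    config: EnvConfig,
) -> np.ndarray:
    """Binary matrix of predicate valuations: rows = pairs, columns = predicates."""
    out = np.zeros((len(pairs), len(predicates)), dtype=bool)
    for i, (belief, op) in enumerate(pairs):
        for j, pred in enumerate(predicates):
            out[i, j] = pred.fn(belief, op, config)
    return out
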