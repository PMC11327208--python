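"""Rule induction: describing demonstrated behavior as a DNF formula.

Demonstrated (belief, operation) pairs are positive examples; the
alternative legal operations in the same beliefs are negatives.  Candidate
formulas are disjunctions of conjunctions of predicate literals, scored by
a geometric prior over formula size times a noisy classification
likelihood, and the best candidate is accepted if the policy it induces
stays within a divergence budget of the policy that generated the
demonstrations.  On failure, the least promising demonstration sub-cluster
is dropped and the search retried — the data-selection behavior that lets
an incomplete predicate vocabulary still describe the describable part of
a strategy.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .clustering import DemoSet
from .dsl import Predicate, valuation_matrix
from .env import (
    TERM,
    BeliefState,
    EnvConfig,
    Policy,
    StatelessPolicy,
    estimate_J,
    legal_operations,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# DNF formulas
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Literal:
    """A predicate or its negation inside a conjunction."""

    name: str
    positive: bool = True

    def __str__(self) -> str:
        return self.name if self.positive else f"not({self.name})"


Conjunction = FrozenSet[Literal]


def _conj_str(conj: Conjunction) -> str:
    if not conj:
        return "True"
    parts = sorted(str(l) for l in conj)
    return " and ".join(parts)


@dataclass(frozen=True)
class DNFFormula:
    """A disjunction of conjunctions of predicate literals.

    ``depth`` is the total literal count across all conjunctions.  An empty
    conjunction is the always-true formula; a formula with no conjunctions
    is always false.  Equality is by canonical string.
    """

    conjunctions: Tuple[Conjunction, ...]

    def __post_init__(self) -> None:
        for conj in self.conjunctions:
            names = {l.name for l in conj}
            if len(names) != len(conj):
                raise ValueError(
                    "a conjunction may not contain a predicate and its negation"
                )

    @classmethod
    def from_literals(cls, *conjs: Sequence[Literal]) -> "DNFFormula":
        return cls(tuple(frozenset(c) for c in conjs))

    @classmethod
    def true(cls) -> "DNFFormula":
        return cls((frozenset(),))

    @classmethod
    def false(cls) -> "DNFFormula":
        return cls(())

    @property
    def depth(self) -> int:
        return sum(len(c) for c in self.conjunctions)

    @property
    def is_true(self) -> bool:
        return any(len(c) == 0 for c in self.conjunctions)

    def canonical(self) -> str:
        if not self.conjunctions:
            return "False"
        parts = sorted(_conj_str(c) for c in self.conjunctions)
        if len(parts) == 1:
            return parts[0]
        return " OR ".join(f"({p})" for p in parts)

    def __str__(self) -> str:
        return self.canonical()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DNFFormula) and self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())

    def predicate_names(self) -> Set[str]:
        return {l.name for c in self.conjunctions for l in c}

    def satisfies(
        self,
        belief: BeliefState,
        op: int,
        config: EnvConfig,
        registry: Dict[str, Predicate],
    ) -> bool:
        for conj in self.conjunctions:
            ok = True
            for lit in conj:
                val = registry[lit.name].fn(belief, op, config)
                if bool(val) != lit.positive:
                    ok = False
                    break
            if ok:
                return True
        return False


def registry_of(predicates: Sequence[Predicate]) -> Dict[str, Predicate]:
    return {p.name: p for p in predicates}


class FormulaPolicy(StatelessPolicy):
    """Uniform policy over the legal operations a DNF formula permits.

    If no legal operation satisfies the formula the policy terminates
    (guarantees episodes end; this fallback also shapes the error-model
    likelihoods downstream).
    """

    def __init__(self, dnf: DNFFormula, predicates: Sequence[Predicate],
                 config: EnvConfig):
        self.dnf = dnf
        self.registry = registry_of(predicates)
        self.config = config

    def allowed(self, belief: BeliefState) -> Tuple[int, ...]:
        ops = legal_operations(belief, self.config)
        sat = tuple(o for o in ops
                    if self.dnf.satisfies(belief, o, self.config, self.registry))
        return sat if sat else (TERM,)

    def probabilities(self, belief: BeliefState) -> Dict[int, float]:
        sat = self.allowed(belief)
        return {o: 1.0 / len(sat) for o in sat}


def formula_policy(dnf: DNFFormula, predicates: Sequence[Predicate],
                   config: EnvConfig) -> FormulaPolicy:
    return FormulaPolicy(dnf, predicates, config)


# ---------------------------------------------------------------------------
# examples
# ---------------------------------------------------------------------------

@dataclass
class ExampleSets:
    """Positive and negative (belief, operation) pairs with valuations."""

    positives: List[Tuple[BeliefState, int]]
    negatives: List[Tuple[BeliefState, int]]

    def __post_init__(self) -> None:
        pos_keys = {(b.clicks, b.values, o) for b, o in self.positives}
        neg_keys = {(b.clicks, b.values, o) for b, o in self.negatives}
        if pos_keys & neg_keys:
            raise ValueError("positive and negative examples overlap")


def build_examples(
    demos: Sequence[Tuple[BeliefState, int]], config: EnvConfig
) -> ExampleSets:
    """Demonstrated pairs are positives; the untaken legal alternatives in
    the demonstrated beliefs are negatives."""
    pos_keys = {(b.clicks, b.values, o) for b, o in demos}
    positives = list(demos)
    negatives: List[Tuple[BeliefState, int]] = []
    seen_neg: Set[Tuple[Tuple[int, ...], Tuple[int, ...], int]] = set()
    for belief, _ in demos:
        for op in legal_operations(belief, config):
            key = (belief.clicks, belief.values, op)
            if key in pos_keys or key in seen_neg:
                continue
            seen_neg.add(key)
            negatives.append((belief, op))
    return ExampleSets(positives=positives, negatives=negatives)


# ---------------------------------------------------------------------------
# divergence
# ---------------------------------------------------------------------------

def divergence(j_formula: float, j_interpreted: float, expert_reward: float) -> float:
    """|J(pi_formula) - J(pi_interpreted)| / J(pi_optimal).

    The absolute difference is used: a formula policy that out-earns the
    policy it is meant to imitate is just as much of a mis-imitation as one
    that under-earns it.
    """
    if expert_reward == 0:
        raise ValueError("expert_reward must be non-zero")
    return abs(j_formula - j_interpreted) / expert_reward


# ---------------------------------------------------------------------------
# LPP-style search
# ---------------------------------------------------------------------------

#: geometric decay of the formula prior per literal
GAMMA_LIT = 0.5
#: probability that a single example is classified correctly under the
#: noisy-classification likelihood
P_CORRECT = 0.9


@dataclass(order=True)
class ScoredFormula:
    neg_score: float
    n_conjunctions: int
    canonical: str
    formula: DNFFormula = field(compare=False)

    @property
    def score(self) -> float:
        return -self.neg_score


def _score(w_correct: float, w_total: float, n_literals: int) -> float:
    """Log posterior score: size prior times classification likelihood.

    ``w_correct``/``w_total`` are class-balanced example weights: every
    demonstrated belief contributes one positive but all its untaken legal
    alternatives as negatives, so unweighted counts would reward formulas
    that reject operations inside the demonstrated policy's own support.
    """
    return (
        n_literals * math.log(GAMMA_LIT)
        + w_correct * math.log(P_CORRECT)
        + (w_total - w_correct) * math.log(1.0 - P_CORRECT)
    )


Signed = Tuple[int, bool]          # predicate index, sign
ConjIdx = Tuple[Signed, ...]       # a conjunction as signed predicate indices


def _conj_pos_mask(conj: ConjIdx, V: np.ndarray) -> np.ndarray:
    m = np.ones(V.shape[0], dtype=bool)
    for j, sign in conj:
        m &= V[:, j] == sign
    return m


def _to_formula(conjs: Sequence[ConjIdx],
                predicates: Sequence[Predicate]) -> DNFFormula:
    return DNFFormula(tuple(
        frozenset(Literal(predicates[j].name, sign) for j, sign in conj)
        for conj in conjs
    ))


def _enumerate_conjunctions_by_size(
    n_preds: int, max_literals: int
) -> Dict[int, List[ConjIdx]]:
    out: Dict[int, List[ConjIdx]] = {}
    for size in range(1, max_literals + 1):
        bucket: List[ConjIdx] = []
        for idxs in itertools.combinations(range(n_preds), size):
            for signs in itertools.product((True, False), repeat=size):
                bucket.append(tuple(zip(idxs, signs)))
        out[size] = bucket
    return out


def _size_multisets(budget: int) -> List[Tuple[int, ...]]:
    """Non-increasing integer partitions with sum <= budget (conjunction sizes)."""
    out: List[Tuple[int, ...]] = []

    def rec(prefix: Tuple[int, ...], remaining: int, max_part: int) -> None:
        if prefix:
            out.append(prefix)
        for part in range(min(remaining, max_part), 0, -1):
            rec(prefix + (part,), remaining - part, part)

    rec((), budget, budget)
    return out


def _exact_space_size(counts: Dict[int, int], d: int) -> int:
    total = 0
    for sizes in _size_multisets(d):
        combo = 1
        for size, mult in {s: sizes.count(s) for s in set(sizes)}.items():
            combo *= math.comb(counts.get(size, 0), mult)
        total += combo
        if total > 10**8:
            break
    return total


def lpp_search(
    examples: ExampleSets,
    predicates: Sequence[Predicate],
    d: int,
    config: EnvConfig,
    top_k: int = 10,
    exact_cap: int = 100_000,
    max_conj_literals: int | None = None,
) -> List[ScoredFormula]:
    """Rank depth-bounded DNF formulas by prior x classification likelihood.

    The prior decays geometrically in the literal count; the likelihood
    counts accepted positives and rejected negatives as correct.  When the
    bounded formula space is small the search is exhaustive; otherwise
    candidates are grown greedily (best conjunction by literal-level
    growth, then further conjunctions covering residual positives, then
    local pruning).  Returns candidates sorted best-first; empty if no
    candidate accepts any positive example.
    """
    if not examples.positives:
        raise ValueError("at least one positive example is required")
    V_pos = valuation_matrix(examples.positives, predicates, config)
    V_neg = valuation_matrix(examples.negatives, predicates, config)
    n_pos, n_neg = len(examples.positives), len(examples.negatives)
    # class balancing: total positive weight equals total negative weight
    w_pos = (n_neg / n_pos) if n_neg else 1.0
    w_total = w_pos * n_pos + n_neg
    n_preds = len(predicates)
    if max_conj_literals is None:
        max_conj_literals = d

    results: Dict[str, ScoredFormula] = {}

    def covers(conjs: Sequence[ConjIdx]) -> Tuple[np.ndarray, np.ndarray]:
        pos = np.zeros(V_pos.shape[0], dtype=bool)
        neg = np.zeros(V_neg.shape[0], dtype=bool)
        for c in conjs:
            pos |= _conj_pos_mask(c, V_pos)
            neg |= _conj_pos_mask(c, V_neg)
        return pos, neg

    def dnf_score(conjs: Sequence[ConjIdx]) -> float:
        pos, neg = covers(conjs)
        w_correct = w_pos * float(pos.sum()) + float((~neg).sum())
        return _score(w_correct, w_total, sum(len(c) for c in conjs))

    def record(conjs: Sequence[ConjIdx]) -> None:
        if sum(len(c) for c in conjs) > d:
            return
        pos, _ = covers(conjs)
        if not pos.any():
            return  # must accept at least one positive
        f = _to_formula(conjs, predicates)
        sf = ScoredFormula(-dnf_score(conjs), len(conjs), f.canonical(), f)
        prev = results.get(sf.canonical)
        if prev is None or sf < prev:
            results[sf.canonical] = sf

    max_size = min(d, max_conj_literals)
    counts = {s: math.comb(n_preds, s) * 2**s for s in range(1, max_size + 1)}

    if _exact_space_size(counts, d) <= exact_cap:
        by_size = _enumerate_conjunctions_by_size(n_preds, max_size)
        for sizes in _size_multisets(d):
            if any(s not in by_size for s in sizes):
                continue
            mult = {s: sizes.count(s) for s in set(sizes)}
            pools = [itertools.combinations(by_size[s], m)
                     for s, m in sorted(mult.items())]
            for groups in itertools.product(*pools):
                sel = [c for g in groups for c in g]
                record(sel)
    else:
        _greedy_search(V_pos, d, dnf_score, record)

    # the trivial always-true formula (random clicking) is always in the
    # space: it accepts every positive at zero prior cost in literals
    true_formula = DNFFormula.true()
    results.setdefault(
        true_formula.canonical(),
        ScoredFormula(-_score(w_pos * n_pos, w_total, 0), 1,
                      true_formula.canonical(), true_formula))

    ranked = sorted(results.values())
    return ranked[:top_k]


def _greedy_search(V_pos, d, dnf_score, record) -> None:
    """Greedy DNF construction: grow a conjunction literal by literal, then
    add further conjunctions for residual positives, then prune."""
    literals: List[Signed] = [(j, s) for j in range(V_pos.shape[1])
                              for s in (True, False)]

    def grow_conjunction(selected: List[ConjIdx], budget: int) -> ConjIdx | None:
        conj: ConjIdx = ()
        best_score = -math.inf
        while len(conj) < budget:
            best_lit, best_s = None, best_score
            used = {j for j, _ in conj}
            for j, s in literals:
                if j in used:
                    continue
                trial = conj + ((j, s),)
                sc = dnf_score(selected + [trial])
                if sc > best_s:
                    best_lit, best_s = (j, s), sc
            if best_lit is None:
                break
            conj = conj + (best_lit,)
            best_score = best_s
            record(selected + [conj])
        return conj if conj else None

    sel: List[ConjIdx] = []
    while sum(len(c) for c in sel) < d:
        budget = d - sum(len(c) for c in sel)
        base = dnf_score(sel) if sel else -math.inf
        nxt = grow_conjunction(sel, budget)
        if nxt is None or (sel and dnf_score(sel + [nxt]) <= base):
            break
        sel.append(nxt)
        record(sel)
    # local pruning: drop whole conjunctions or single literals if it helps
    improved = True
    while improved and sel:
        improved = False
        base = dnf_score(sel)
        for i, conj in enumerate(sel):
            trial = sel[:i] + sel[i + 1:]
            if trial and dnf_score(trial) > base:
                sel, improved = trial, True
                record(sel)
                break
            for k in range(len(conj)):
                shorter = conj[:k] + conj[k + 1:]
                trial2 = sel[:i] + ([shorter] if shorter else []) + sel[i + 1:]
                if trial2 and dnf_score(trial2) > base:
                    sel, improved = trial2, True
                    record(sel)
                    break
            if improved:
                break


# ---------------------------------------------------------------------------
# the interpretation loop
# ---------------------------------------------------------------------------

@dataclass
class InterpretParams:
    """Knobs of the imitation-learning loop.

    ``expert_reward`` is J of the optimal metalevel policy for the
    environment (a known benchmark constant, e.g. 39.97 for the default
    increasing-variance web); ``max_divergence`` is the acceptance budget
    alpha on |J(pi_f) - J(pi_bar)| / expert_reward.
    """

    depth: int = 6
    max_divergence: float = 0.2
    num_rollouts: int = 32
    num_ai_clusters: int = 3
    expert_reward: float = 39.97

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.max_divergence <= 1:
            raise ValueError("max_divergence must lie in [0, 1]")
        if self.expert_reward <= 0:
            raise ValueError("expert_reward must be > 0")


@dataclass
class InterpretResult:
    """Typed outcome of :func:`interpret`; ``formula`` is None on failure."""

    formula: Optional[DNFFormula]
    used_fraction: float
    j_formula: Optional[float] = None
    j_interpreted: Optional[float] = None
    divergence: Optional[float] = None

    @property
    def success(self) -> bool:
        return self.formula is not None


def _valuation_clusters(
    V: np.ndarray, num_clusters: int
) -> np.ndarray:
    """Agglomerative clustering of valuation vectors (Hamming, average link)."""
    n = V.shape[0]
    k = min(num_clusters, n)
    if k <= 1 or n <= 1:
        return np.zeros(n, dtype=int)
    uniq, inverse = np.unique(V, axis=0, return_inverse=True)
    if len(uniq) <= k:
        return inverse
    Z = linkage(pdist(uniq.astype(float), metric="hamming"), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    return labels[inverse]


def interpret(
    demo_set: DemoSet,
    predicates: Sequence[Predicate],
    params: InterpretParams,
    config: EnvConfig,
    rng: np.random.Generator,
) -> InterpretResult:
    """Find a DNF description of the demonstrations within the divergence budget.

    The demonstrations are partitioned into ``num_ai_clusters`` valuation
    clusters.  Candidates from the DNF search over the retained clusters are
    accepted when their induced policy's Monte-Carlo J estimate stays within
    ``max_divergence`` of the interpreted policy's, proportionally to the
    expert reward.  On failure the cluster with the smallest weighted
    posterior (size x best single-conjunction score) is dropped and the
    search retried; a typed failure is returned when all clusters are
    exhausted.
    """
    pairs = demo_set.pairs
    if not pairs:
        raise ValueError("demo set is empty")
    V = valuation_matrix(pairs, predicates, config)
    labels = _valuation_clusters(V, params.num_ai_clusters)
    active = sorted(set(labels.tolist()))

    j_interp, _ = estimate_J(demo_set.source_policy, config,
                             params.num_rollouts, rng)

    n_all = len(pairs)
    while active:
        keep = np.isin(labels, active)
        kept_pairs = [p for p, k in zip(pairs, keep) if k]
        examples = build_examples(kept_pairs, config)
        candidates = lpp_search(examples, predicates, params.depth, config)
        for cand in candidates:
            pol = formula_policy(cand.formula, predicates, config)
            j_f, _ = estimate_J(pol, config, params.num_rollouts, rng)
            div = divergence(j_f, j_interp, params.expert_reward)
            if div <= params.max_divergence:
                frac = len(kept_pairs) / n_all
                logger.info(
                    "accepted formula %s (div=%.3f, used %.0f%% of demos)",
                    cand.formula, div, 100 * frac)
                return InterpretResult(cand.formula, frac, j_f, j_interp, div)
        # drop the least promising cluster: smallest size x best score
        def cluster_weight(c: int) -> float:
            sub = [p for p, l in zip(pairs, labels) if l == c]
            ex = build_examples(sub, config)
            best = lpp_search(ex, predicates, min(params.depth, 2), config, top_k=1)
            s = best[0].score if best else -math.inf
            return len(sub) * math.exp(min(s, 0.0))

        worst = min(active, key=cluster_weight)
        logger.info("dropping demonstration cluster %d", worst)
        active.remove(worst)

    return InterpretResult(None, 0.0, None, j_interp, None)
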