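"""Temporal ordering of DNF descriptions.

A DNF formula says *which* operations a strategy permits; it does not say
in what order its conjunctions apply.  This module converts a DNF into a
*procedural formula*: an ordered sequence of steps, each a conjunction to
follow UNTIL a state-level condition occurs (UNLESS another condition
occurs), with NEXT between steps and an optional GOTO loop.  Phase
structure is read off the demonstrations: conjunctions are ordered by
first activation, and each phase's UNTIL condition is the condition-pool
element that is false throughout the phase and true exactly at its end in
the largest fraction of demonstration rollouts (falling back to the
special "until it stops applying" operator).  A final greedy pruning pass
deletes literals whenever that increases the likelihood of the human
planning operations under the induced policy.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .dnf_learning import Conjunction, DNFFormula, Literal, registry_of
from .dsl import Predicate
from .env import TERM, BeliefState, EnvConfig, legal_operations

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Condition:
    """An UNTIL/UNLESS condition: a state-level predicate or a 2-disjunction."""

    predicates: Tuple[Predicate, ...]  # 1 or 2 elements

    @property
    def name(self) -> str:
        if len(self.predicates) == 1:
            return self.predicates[0].name
        names = sorted(p.name for p in self.predicates)
        return f"({names[0]} or {names[1]})"

    def holds(self, belief: BeliefState, config: EnvConfig) -> bool:
        return any(p.fn(belief, TERM, config) for p in self.predicates)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Condition) and other.name == self.name

    def __hash__(self) -> int:
        return hash(self.name)


class StopsApplying:
    """The special UNTIL operator: follow the step while it still applies."""

    def __repr__(self) -> str:
        return "UNTIL_IT_STOPS_APPLYING"


UNTIL_STOPS = StopsApplying()


@dataclass(frozen=True)
class Goto:
    target: int  # 0-based step index
    unless: Condition


@dataclass(frozen=True)
class Step:
    conjunction: Conjunction  # empty frozenset = True
    until: Condition | StopsApplying
    unless: Optional[Condition] = None


@dataclass(frozen=True)
class ProceduralFormula:
    """Temporally ordered, NL-translatable form of a strategy description."""

    steps: Tuple[Step, ...]
    goto: Optional[Goto] = None

    def canonical(self) -> str:
        parts = []
        for k, s in enumerate(self.steps):
            if s.conjunction:
                conj = " and ".join(sorted(str(l) for l in s.conjunction))
            else:
                conj = "True"
            if isinstance(s.until, StopsApplying):
                u = "UNTIL IT STOPS APPLYING"
            else:
                u = f"UNTIL {s.until.name}"
            line = f"STEP {k + 1}: {conj} {u}"
            if s.unless is not None:
                line += f" UNLESS {s.unless.name}"
            if k + 1 < len(self.steps):
                line += " NEXT"
            elif self.goto is not None:
                line += (f" GOTO {self.goto.target + 1}"
                         f" UNLESS {self.goto.unless.name}")
            parts.append(line)
        return "\n".join(parts)

    def __str__(self) -> str:
        return self.canonical()

    def predicate_names(self) -> Set[str]:
        names = {l.name for s in self.steps for l in s.conjunction}
        for s in self.steps:
            if isinstance(s.until, Condition):
                names |= {p.name for p in s.until.predicates}
            if s.unless is not None:
                names |= {p.name for p in s.unless.predicates}
        if self.goto is not None:
            names |= {p.name for p in self.goto.unless.predicates}
        return names

    def flatten(self) -> DNFFormula:
        """Forget the temporal structure: the disjunction of all step conjunctions."""
        return DNFFormula(tuple(s.conjunction for s in self.steps))


def condition_pool(predicates: Sequence[Predicate]) -> List[Condition]:
    """All state-level predicates plus their pairwise disjunctions.

    Every printed UNTIL/UNLESS condition in the benchmark is state-level
    ("all the leaves are observed or the previously observed node uncovers
    a 48"), so action-level predicates are excluded.  Singles come before
    disjunctions; within each group the order is lexicographic — this is
    also the tie-break order for phase-boundary scoring.
    """
    singles = sorted((p for p in predicates if p.state_level),
                     key=lambda p: p.name)
    pool = [Condition((p,)) for p in singles]
    for a, b in itertools.combinations(singles, 2):
        pool.append(Condition((a, b)))
    return pool


# ---------------------------------------------------------------------------
# procedural policy (step tracker)
# ---------------------------------------------------------------------------

class ProceduralPolicy:
    """Policy induced by a procedural formula, with a per-episode step tracker.

    At each belief the active step's conjunction defines the allowed
    operations (uniform over them; TERM if none).  After every operation
    the tracker advances: past an UNTIL condition once it holds in the new
    belief, past an UNLESS condition immediately, and through the GOTO loop
    while its exit condition is false.  "Until it stops applying" advances
    when the step's conjunction no longer permits any legal operation.
    """

    def __init__(self, formula: ProceduralFormula,
                 predicates: Sequence[Predicate], config: EnvConfig):
        self.formula = formula
        self.registry = registry_of(predicates)
        self.config = config

    def episode(self) -> "_ProceduralEpisode":
        return _ProceduralEpisode(self)

    # -- step-level helpers -------------------------------------------------

    def step_allowed(self, step_idx: int, belief: BeliefState) -> Tuple[int, ...]:
        if step_idx >= len(self.formula.steps):
            return (TERM,)
        conj = self.formula.steps[step_idx].conjunction
        ops = legal_operations(belief, self.config)
        sat = tuple(
            o for o in ops
            if all(self.registry[l.name].fn(belief, o, self.config) == l.positive
                   for l in conj)
        )
        return sat if sat else (TERM,)

    def advance_step(self, step_idx: int, belief: BeliefState) -> int:
        """Resolve which step is active in ``belief`` starting from ``step_idx``."""
        formula = self.formula
        guard = 0
        while guard < 4 * max(len(formula.steps), 1):
            guard += 1
            if step_idx >= len(formula.steps):
                if formula.goto is not None and not formula.goto.unless.holds(
                        belief, self.config):
                    step_idx = formula.goto.target
                    continue
                return step_idx
            step = formula.steps[step_idx]
            if step.unless is not None and step.unless.holds(belief, self.config):
                step_idx += 1
                continue
            if isinstance(step.until, StopsApplying):
                ops = legal_operations(belief, self.config)
                applies = any(
                    all(self.registry[l.name].fn(belief, o, self.config)
                        == l.positive for l in step.conjunction)
                    for o in ops
                ) or not step.conjunction
                if not applies:
                    step_idx += 1
                    continue
                return step_idx
            if step.until.holds(belief, self.config):
                step_idx += 1
                continue
            return step_idx
        return step_idx


class _ProceduralEpisode:
    def __init__(self, policy: ProceduralPolicy):
        self.policy = policy
        self.step_idx = policy.advance_step(0, BeliefState())

    def probabilities(self, belief: BeliefState) -> Dict[int, float]:
        allowed = self.policy.step_allowed(self.step_idx, belief)
        return {o: 1.0 / len(allowed) for o in allowed}

    def advance(self, belief: BeliefState, op: int, next_belief: BeliefState) -> None:
        self.step_idx = self.policy.advance_step(self.step_idx, next_belief)


def allowed_operations_along(
    policy: ProceduralPolicy,
    steps: Sequence[Tuple[BeliefState, int]],
) -> List[Tuple[int, ...]]:
    """Allowed-operation sets at each step of a trajectory, tracking phases."""
    ep = policy.episode()
    out: List[Tuple[int, ...]] = []
    for belief, op in steps:
        ep.step_idx = policy.advance_step(ep.step_idx, belief)
        out.append(policy.step_allowed(ep.step_idx, belief))
    return out


def trajectory_loglik(
    policy: ProceduralPolicy,
    steps: Sequence[Tuple[BeliefState, int]],
) -> float:
    """Sum of log P(op | induced policy) along one trajectory.

    Disallowed operations receive a floor probability so pruning can
    compare formulas that reject some human operations.
    """
    total = 0.0
    floor = 1e-6
    for allowed, (belief, op) in zip(
            allowed_operations_along(policy, steps), steps):
        p = 1.0 / len(allowed) if op in allowed else floor
        total += math.log(p)
    return total


# ---------------------------------------------------------------------------
# DNF -> procedural conversion
# ---------------------------------------------------------------------------

class ConversionError(ValueError):
    pass


def _phases_of_rollout(
    rollout_steps: Sequence[Tuple[BeliefState, int]],
    dnf: DNFFormula,
    registry: Dict[str, Predicate],
    config: EnvConfig,
) -> List[Tuple[int, List[Tuple[BeliefState, int]], BeliefState]]:
    """Split one rollout into (conjunction index, steps, end belief) phases.

    Each demonstrated operation is assigned to the first conjunction it
    satisfies.  A trailing TERM that satisfies no conjunction ends the last
    phase (its belief is the phase-end belief); any other uncovered
    operation is a precondition violation.
    """
    assignments: List[Tuple[int, BeliefState, int]] = []
    offenders: List[Tuple[Tuple[int, ...], int]] = []
    for belief, op in rollout_steps:
        idx = None
        for k, conj in enumerate(dnf.conjunctions):
            if all(registry[l.name].fn(belief, op, config) == l.positive
                   for l in conj):
                idx = k
                break
        if idx is None:
            if op == TERM:
                idx = -1  # terminator marker
            else:
                offenders.append((belief.clicks, op))
                continue
        assignments.append((idx, belief, op))
    if offenders:
        raise ConversionError(
            f"demonstrated operations not covered by any conjunction: {offenders}")

    phases: List[Tuple[int, List[Tuple[BeliefState, int]], BeliefState]] = []
    for idx, belief, op in assignments:
        if idx == -1:
            break
        if phases and phases[-1][0] == idx:
            phases[-1][1].append((belief, op))
        else:
            phases.append((idx, [(belief, op)], belief))
    # end belief of each phase = belief at the start of the next phase, or the
    # belief in which the rollout terminated
    ends: List[BeliefState] = []
    for i, (idx, steps, _) in enumerate(phases):
        if i + 1 < len(phases):
            ends.append(phases[i + 1][1][0][0])
        else:
            last_belief, last_op = rollout_steps[-1]
            ends.append(last_belief)
    return [(idx, steps, end) for (idx, steps, _), end in zip(phases, ends)]


def _detect_cycle(seq: Sequence[int]) -> Optional[int]:
    """Shortest period p (>=2 phases repeating) if ``seq`` is periodic."""
    n = len(seq)
    for p in range(1, n):
        if n // p < 2 or n % p not in (0,):
            continue
        if all(seq[i] == seq[i % p] for i in range(n)):
            if n > p:
                return p
    return None


def _condition_score(
    cond: Condition,
    phase_records: Sequence[Tuple[List[Tuple[BeliefState, int]], BeliefState]],
    config: EnvConfig,
) -> float:
    """Fraction of rollouts where the condition is false throughout the phase
    and true exactly at the phase end."""
    hits = 0
    for steps, end_belief in phase_records:
        if any(cond.holds(b, config) for b, _ in steps):
            continue
        if cond.holds(end_belief, config):
            hits += 1
    return hits / len(phase_records)


def _pool_rank(pool: Sequence[Condition]) -> Dict[str, int]:
    return {c.name: i for i, c in enumerate(pool)}


def _simplify_conjunction(
    conj: Conjunction,
    until: Condition | StopsApplying,
    previous_until: Optional[Condition],
    phase_beliefs: Sequence[BeliefState],
    registry: Dict[str, Predicate],
    config: EnvConfig,
) -> Conjunction:
    """Canonical cleanups justified by the temporal structure.

    1. A literal asserting the previous step's UNTIL condition is implied by
       step order and dropped.
    2. A literal negating (a disjunct of) this step's own UNTIL condition is
       absorbed by the UNTIL operator and dropped.
    3. If the remainder permits every legal operation at every belief seen
       in the phase, the step denotes complete uncertainty: True.
    4. A step that only ever permits termination denotes stopping; any
       qualifiers beyond the termination literal are dropped.
    """
    out = set(conj)
    if previous_until is not None and len(previous_until.predicates) == 1:
        name = previous_until.predicates[0].name
        out = {l for l in out if not (l.positive and l.name == name)}
    if isinstance(until, Condition):
        until_names = {p.name for p in until.predicates}
        out = {l for l in out if not (not l.positive and l.name in until_names)}
    if out and phase_beliefs:
        def satisfying(b: BeliefState) -> set:
            return {o for o in legal_operations(b, config)
                    if all(registry[l.name].fn(b, o, config) == l.positive
                           for l in out)}

        sat_sets = [satisfying(b) for b in phase_beliefs]
        if all(s == set(legal_operations(b, config))
               for s, b in zip(sat_sets, phase_beliefs)):
            out = set()
        elif all(s == {TERM} for s in sat_sets):
            out = {Literal("is_term", True)}
    return frozenset(out)


def dnf_to_procedural(
    dnf: DNFFormula,
    demos: Sequence[Sequence[Tuple[BeliefState, int]]],
    pool: Sequence[Condition],
    predicates: Sequence[Predicate],
    config: EnvConfig,
    min_support: float = 0.5,
) -> ProceduralFormula:
    """Order the DNF's conjunctions temporally using demonstration rollouts.

    ``demos`` are rollouts (lists of (belief, operation) pairs).  Raises
    :class:`ConversionError` if a demonstrated non-TERM operation satisfies
    no conjunction.
    """
    if not demos:
        raise ConversionError("at least one demonstration rollout is required")
    registry = registry_of(predicates)
    per_rollout = [_phases_of_rollout(r, dnf, registry, config) for r in demos]
    per_rollout = [p for p in per_rollout if p]
    if not per_rollout:
        # demonstrations contain only immediate TERM: a single True step
        return ProceduralFormula(
            steps=(Step(frozenset(), UNTIL_STOPS),))

    # modal phase template (most common conjunction-index sequence)
    sequences = [tuple(idx for idx, _, _ in phases) for phases in per_rollout]
    counts: Dict[Tuple[int, ...], int] = {}
    for s in sequences:
        counts[s] = counts.get(s, 0) + 1
    template = max(counts, key=lambda s: (counts[s], len(s)))

    goto: Optional[Goto] = None
    period = _detect_cycle(template)
    template_idx = list(template)
    if period is not None:
        template_idx = list(template[:period])

    rank = _pool_rank(pool)
    steps: List[Step] = []
    previous_until: Optional[Condition] = None
    matching = [phases for phases, seq in zip(per_rollout, sequences)]

    for pos, conj_idx in enumerate(template_idx):
        # collect this phase across rollouts whose sequence starts compatibly
        records: List[Tuple[List[Tuple[BeliefState, int]], BeliefState]] = []
        for phases, seq in zip(per_rollout, sequences):
            for occurrence, (idx, ph_steps, end) in enumerate(phases):
                if idx == conj_idx:
                    records.append((ph_steps, end))
                    break
        if not records:
            continue
        best: Optional[Condition] = None
        best_score = 0.0
        for cond in pool:
            s = _condition_score(cond, records, config)
            if s > best_score or (
                    s == best_score and best is not None and s > 0
                    and rank[cond.name] < rank[best.name]):
                best, best_score = cond, s
        until: Condition | StopsApplying
        if best is not None and best_score >= min_support:
            until = best
        else:
            until = UNTIL_STOPS
        phase_beliefs = [b for ph, _ in records for b, _ in ph]
        conj = _simplify_conjunction(
            dnf.conjunctions[conj_idx], until, previous_until,
            phase_beliefs, registry, config)
        steps.append(Step(conj, until))
        previous_until = until if isinstance(until, Condition) else None

    if period is not None:
        # loop exit: condition true at the final belief of the rollouts
        final_records = [(sum((ph for _, ph, _ in phases), []), phases[-1][2])
                         for phases in per_rollout]
        exit_cond: Optional[Condition] = None
        best_frac = 0.0
        for cond in pool:
            frac = sum(
                1 for _, end in final_records if cond.holds(end, config)
            ) / len(final_records)
            if frac > best_frac or (
                    frac == best_frac and exit_cond is not None and frac > 0
                    and rank[cond.name] < rank[exit_cond.name]):
                exit_cond, best_frac = cond, frac
        if exit_cond is not None and best_frac >= min_support:
            goto = Goto(target=0, unless=exit_cond)

    if not steps:
        steps = [Step(frozenset(), UNTIL_STOPS)]
    return ProceduralFormula(steps=tuple(steps), goto=goto)


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def _removable(formula: ProceduralFormula) -> List[Tuple[int, Literal]]:
    out = []
    for i, s in enumerate(formula.steps):
        for lit in sorted(s.conjunction, key=str):
            out.append((i, lit))
    return out


def _without(formula: ProceduralFormula, step_idx: int,
             lit: Literal) -> ProceduralFormula:
    steps = list(formula.steps)
    s = steps[step_idx]
    steps[step_idx] = replace(s, conjunction=s.conjunction - {lit})
    return ProceduralFormula(tuple(steps), formula.goto)


def prune(
    procedural: ProceduralFormula,
    human_trajectories: Sequence[Sequence[Tuple[BeliefState, int]]],
    predicates: Sequence[Predicate],
    config: EnvConfig,
) -> ProceduralFormula:
    """Greedily delete literals to raise the likelihood of human operations.

    One literal is removed per iteration — the deletion with the largest
    strict increase in total log-likelihood under the induced policy; ties
    keep the literal.  The returned formula's likelihood is never below the
    input's.
    """
    if not human_trajectories:
        raise ValueError("human operations must be non-empty")

    def loglik(f: ProceduralFormula) -> float:
        pol = ProceduralPolicy(f, predicates, config)
        return sum(trajectory_loglik(pol, t) for t in human_trajectories)

    current = procedural
    current_ll = loglik(current)
    while True:
        best: Optional[ProceduralFormula] = None
        best_ll = current_ll
        for step_idx, lit in _removable(current):
            trial = _without(current, step_idx, lit)
            ll = loglik(trial)
            if ll > best_ll:
                best, best_ll = trial, ll
        if best is None:
            return current
        logger.debug("prune: %.3f -> %.3f", current_ll, best_ll)
        current, current_ll = best, best_ll
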