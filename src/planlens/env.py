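"""Metalevel Mouselab-MDP environment.

The task externalizes planning as paid information gathering: a participant
faces a directed graph of occluded nodes, may click nodes to reveal the
rewards hidden underneath (paying a fixed fee per click), and finally commits
to traversing the start-to-leaf path with the highest expected sum of rewards.
The *belief state* is the set of revealed nodes; a *planning operation* is a
click or the decision to stop planning (``TERM``).

The default configuration is the increasing-variance web used throughout this
package: 3 branches, each a depth-1 -> depth-2 -> two depth-3 leaves chain
(12 clickable nodes, 6 paths), with per-depth reward supports
{-4,-2,2,4} / {-8,-4,4,8} / {-48,-24,24,48} and a click cost of 1.  Episodes
are finite and undiscounted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from typing import Dict, Mapping, Protocol, Tuple

import numpy as np

#: Distinguished planning operation: stop planning and commit to a path.
TERM: int = 0


class ConfigError(ValueError):
    """Raised for an ill-formed environment configuration."""


class IllegalOperationError(ValueError):
    """Raised when a planning operation is not legal in the given belief."""


@dataclass(frozen=True)
class EnvConfig:
    """Layout and reward structure of one Mouselab-MDP environment.

    ``children`` maps each clickable node id (1-based, breadth-first) to its
    child node ids; ``roots`` are the children of the (non-clickable) start
    node.  ``reward_support`` maps node depth (1-based) to the finite set of
    integer rewards that depth can hide.
    """

    children: Mapping[int, Tuple[int, ...]]
    roots: Tuple[int, ...]
    reward_support: Mapping[int, Tuple[int, ...]]
    click_cost: float = 1.0
    #: Carried for completeness; episodes are <= n_nodes + 1 steps, so the
    #: discount is fixed to 1 and never applied.
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.click_cost < 0:
            raise ConfigError("click_cost must be >= 0")
        for node in self.nodes:
            depth = self.depth[node]
            if depth not in self.reward_support:
                raise ConfigError(f"no reward support declared for depth {depth}")
            if not self.reward_support[depth]:
                raise ConfigError(f"empty reward support at depth {depth}")
        # every clickable node must lie on >= 1 start->leaf path
        on_path = {n for path in self.paths for n in path}
        missing = set(self.nodes) - on_path
        if missing:
            raise ConfigError(f"nodes not on any root->leaf path: {sorted(missing)}")

    @cached_property
    def nodes(self) -> Tuple[int, ...]:
        """All clickable node ids in breadth-first order."""
        seen: list[int] = []
        frontier = list(self.roots)
        while frontier:
            nxt: list[int] = []
            for n in frontier:
                seen.append(n)
                nxt.extend(self.children.get(n, ()))
            frontier = nxt
        return tuple(seen)

    @cached_property
    def depth(self) -> Dict[int, int]:
        d: Dict[int, int] = {n: 1 for n in self.roots}
        order = [*self.roots]
        while order:
            n = order.pop(0)
            for c in self.children.get(n, ()):
                d[c] = d[n] + 1
                order.append(c)
        return d

    @cached_property
    def parent(self) -> Dict[int, int]:
        p: Dict[int, int] = {}
        for n, cs in self.children.items():
            for c in cs:
                p[c] = n
        return p

    @cached_property
    def leaves(self) -> Tuple[int, ...]:
        return tuple(n for n in self.nodes if not self.children.get(n))

    @cached_property
    def paths(self) -> Tuple[Tuple[int, ...], ...]:
        """All start->leaf paths as tuples of clickable node ids."""
        out: list[Tuple[int, ...]] = []

        def walk(node: int, prefix: Tuple[int, ...]) -> None:
            prefix = prefix + (node,)
            kids = self.children.get(node, ())
            if not kids:
                out.append(prefix)
            else:
                for c in kids:
                    walk(c, prefix)

        for r in self.roots:
            walk(r, ())
        return tuple(out)

    @cached_property
    def siblings(self) -> Dict[int, Tuple[int, ...]]:
        sib: Dict[int, Tuple[int, ...]] = {}
        for n in self.nodes:
            p = self.parent.get(n)
            if p is None:
                others = tuple(m for m in self.roots if m != n)
            else:
                others = tuple(m for m in self.children[p] if m != n)
            sib[n] = others
        return sib

    @cached_property
    def branch_of(self) -> Dict[int, int]:
        """Root node id of the branch each node belongs to."""
        b: Dict[int, int] = {}
        for n in self.nodes:
            m = n
            while m not in self.roots:
                m = self.parent[m]
            b[n] = m
        return b

    @cached_property
    def support_mean(self) -> Dict[int, float]:
        return {
            d: float(np.mean(vals)) for d, vals in self.reward_support.items()
        }

    @property
    def max_depth(self) -> int:
        return max(self.depth.values())

    @property
    def max_reward(self) -> int:
        return max(self.reward_support[self.max_depth])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def default_config() -> EnvConfig:
    """The canonical 12-node increasing-variance environment."""
    children = {
        1: (4,), 2: (5,), 3: (6,),
        4: (7, 8), 5: (9, 10), 6: (11, 12),
        7: (), 8: (), 9: (), 10: (), 11: (), 12: (),
    }
    support = {
        1: (-4, -2, 2, 4),
        2: (-8, -4, 4, 8),
        3: (-48, -24, 24, 48),
    }
    return EnvConfig(children=children, roots=(1, 2, 3), reward_support=support)


GroundTruthRewards = Dict[int, int]


@dataclass(frozen=True)
class BeliefState:
    """Which nodes have been revealed, in click order, and their values.

    Unobserved nodes implicitly carry the uniform distribution over their
    depth's reward support.  ``clicks`` preserves the order of revelation so
    that predicates about the *previously observed* node are well defined.
    """

    clicks: Tuple[int, ...] = ()
    values: Tuple[int, ...] = ()

    @cached_property
    def observed(self) -> Dict[int, int]:
        return dict(zip(self.clicks, self.values))

    def is_observed(self, node: int) -> bool:
        return node in self.observed

    @property
    def last_click(self) -> int | None:
        return self.clicks[-1] if self.clicks else None

    @property
    def last_value(self) -> int | None:
        return self.values[-1] if self.values else None

    def observe(self, node: int, value: int) -> "BeliefState":
        return BeliefState(self.clicks + (node,), self.values + (int(value),))

    def __len__(self) -> int:
        return len(self.clicks)


#: A planning operation: a clickable node id, or TERM (= 0).
PlanningOperation = int


@dataclass(frozen=True)
class Trajectory:
    """One trial's ordered (belief, operation) pairs for one participant."""

    steps: Tuple[Tuple[BeliefState, PlanningOperation], ...]
    participant_id: str = ""
    block: str = ""
    trial_index: int = 0
    ground_truth: Tuple[int, ...] = ()  # rewards in node-id order, optional

    def __post_init__(self) -> None:
        if self.steps and self.steps[-1][1] != TERM:
            raise ValueError("a trajectory must end with TERM")

    @property
    def operations(self) -> Tuple[PlanningOperation, ...]:
        return tuple(op for _, op in self.steps)

    def __len__(self) -> int:
        return len(self.steps)


def legal_operations(belief: BeliefState, config: EnvConfig) -> Tuple[int, ...]:
    """TERM plus every currently unobserved node (re-clicks are illegal)."""
    return (TERM,) + tuple(n for n in config.nodes if n not in belief.observed)


def sample_rewards(config: EnvConfig, rng: np.random.Generator) -> GroundTruthRewards:
    """Draw each node's hidden reward i.i.d. uniform from its depth's support."""
    out: GroundTruthRewards = {}
    for node in config.nodes:
        support = config.reward_support[config.depth[node]]
        out[node] = int(support[rng.integers(len(support))])
    return out


def term_reward(belief: BeliefState, config: EnvConfig) -> float:
    """Expected payoff of committing to the best path under the current belief.

    Each path's expectation sums observed values and support means of
    unobserved nodes; the maximum over paths is returned.
    """
    obs = belief.observed
    best = -math.inf
    for path in config.paths:
        total = 0.0
        for n in path:
            total += obs[n] if n in obs else config.support_mean[config.depth[n]]
        best = max(best, total)
    return best


def best_path(belief: BeliefState, config: EnvConfig) -> Tuple[int, ...]:
    """The (first) path attaining the current termination reward."""
    obs = belief.observed
    best_val, best_p = -math.inf, config.paths[0]
    for path in config.paths:
        total = sum(
            obs[n] if n in obs else config.support_mean[config.depth[n]]
            for n in path
        )
        if total > best_val:
            best_val, best_p = total, path
    return best_p


def transition(
    belief: BeliefState,
    op: PlanningOperation,
    ground_truth: GroundTruthRewards,
    config: EnvConfig,
) -> Tuple[BeliefState, float]:
    """Apply one planning operation; return the new belief and step reward."""
    if op == TERM:
        return belief, term_reward(belief, config)
    if op not in config.depth:
        raise IllegalOperationError(f"unknown node id {op}")
    if belief.is_observed(op):
        raise IllegalOperationError(f"node {op} is already observed")
    return belief.observe(op, ground_truth[op]), -config.click_cost


class EpisodePolicy(Protocol):
    """Per-episode view of a policy: may carry within-episode state."""

    def probabilities(self, belief: BeliefState) -> Dict[int, float]:
        """Distribution over legal planning operations in ``belief``."""
        ...

    def advance(self, belief: BeliefState, op: int, next_belief: BeliefState) -> None:
        """Notify the policy that ``op`` was taken (default: no-op)."""
        ...


class Policy(Protocol):
    def episode(self) -> EpisodePolicy:
        ...


class StatelessPolicy:
    """Base for policies whose action distribution depends only on the belief."""

    def episode(self) -> "StatelessPolicy":
        return self

    def advance(self, belief: BeliefState, op: int, next_belief: BeliefState) -> None:
        return None

    def probabilities(self, belief: BeliefState) -> Dict[int, float]:  # pragma: no cover
        raise NotImplementedError


def sample_operation(
    probs: Dict[int, float], rng: np.random.Generator
) -> int:
    ops = list(probs)
    p = np.asarray([probs[o] for o in ops], dtype=float)
    p = p / p.sum()
    return int(ops[rng.choice(len(ops), p=p)])


def rollout(
    policy: Policy,
    config: EnvConfig,
    rng: np.random.Generator,
    ground_truth: GroundTruthRewards | None = None,
    max_steps: int | None = None,
) -> Tuple[Tuple[Tuple[BeliefState, int], ...], float]:
    """Simulate one episode; returns the (belief, operation) steps and return."""
    if ground_truth is None:
        ground_truth = sample_rewards(config, rng)
    if max_steps is None:
        max_steps = config.n_nodes + 1
    ep = policy.episode()
    belief = BeliefState()
    steps: list[Tuple[BeliefState, int]] = []
    total = 0.0
    for _ in range(max_steps):
        probs = ep.probabilities(belief)
        legal = set(legal_operations(belief, config))
        if not probs or not set(probs) <= legal:
            bad = sorted(set(probs) - legal)
            raise IllegalOperationError(
                f"policy emitted illegal operation(s) {bad} in belief {belief.clicks}"
            )
        op = sample_operation(probs, rng)
        steps.append((belief, op))
        next_belief, r = transition(belief, op, ground_truth, config)
        total += r
        ep.advance(belief, op, next_belief)
        if op == TERM:
            return tuple(steps), total
        belief = next_belief
    # safety: force termination
    steps.append((belief, TERM))
    total += term_reward(belief, config)
    return tuple(steps), total


def estimate_J(
    policy: Policy,
    config: EnvConfig,
    n_rollouts: int,
    rng: np.random.Generator,
) -> Tuple[float, float]:
    """Monte-Carlo estimate of the expected episode return J(pi).

    Returns ``(mean, standard_error)`` over ``n_rollouts`` episodes, each with
    freshly sampled ground-truth rewards.
    """
    if n_rollouts <= 0:
        raise ValueError("n_rollouts must be >= 1")
    returns = np.empty(n_rollouts)
    for i in range(n_rollouts):
        _, returns[i] = rollout(policy, config, rng)
    se = float(returns.std(ddof=1) / math.sqrt(n_rollouts)) if n_rollouts > 1 else 0.0
    return float(returns.mean()), se


class UniformRandomPolicy(StatelessPolicy):
    """Uniform over all legal operations, including TERM."""

    def __init__(self, config: EnvConfig):
        self.config = config

    def probabilities(self, belief: BeliefState) -> Dict[int, float]:
        ops = legal_operations(belief, self.config)
        return {o: 1.0 / len(ops) for o in ops}


class ImmediateTermPolicy(StatelessPolicy):
    """Never clicks."""

    def probabilities(self, belief: BeliefState) -> Dict[int, float]:
        return {TERM: 1.0}
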