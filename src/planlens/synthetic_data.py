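"""Synthetic process-tracing datasets with known strategy labels.

The generator emulates the statistical structure of a Mouselab-MDP
benchmark study: 180 participants x 30 trials (a 20-trial training block
and a 10-trial test block), each participant committed to one named
planning strategy, with i.i.d. per-step lapse noise (a step is replaced by
a uniformly random legal operation with the lapse probability).  The
built-in strategies mirror the strategy families the benchmark analysis
reports — explore leaves until the maximum reward appears, the same with a
sibling preference, no planning, and random planning — with mixing
proportions proportional to the reported frequencies of those four
families.  Latent per-participant labels are stored separately from the
trajectory table so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np

from .env import (
    TERM,
    BeliefState,
    EnvConfig,
    StatelessPolicy,
    Trajectory,
    legal_operations,
    sample_rewards,
    transition,
)


class LeafUntilMaxPolicy(StatelessPolicy):
    """Click unobserved leaves (uniformly) until the maximum reward is
    revealed or the leaves are exhausted; then terminate."""

    def __init__(self, config: EnvConfig):
        self.config = config

    def probabilities(self, belief: BeliefState) -> Dict[int, float]:
        if self.config.max_reward in belief.observed.values():
            return {TERM: 1.0}
        open_leaves = [l for l in self.config.leaves if l not in belief.observed]
        if not open_leaves:
            return {TERM: 1.0}
        return {l: 1.0 / len(open_leaves) for l in open_leaves}


class SiblingLeafPolicy(StatelessPolicy):
    """As :class:`LeafUntilMaxPolicy` but, after the first click, prefer an
    unobserved sibling of the previously observed node when one exists."""

    def __init__(self, config: EnvConfig):
        self.config = config

    def probabilities(self, belief: BeliefState) -> Dict[int, float]:
        c = self.config
        if c.max_reward in belief.observed.values():
            return {TERM: 1.0}
        open_leaves = [l for l in c.leaves if l not in belief.observed]
        if not open_leaves:
            return {TERM: 1.0}
        prev = belief.last_click
        if prev is not None:
            sibs = [s for s in c.siblings.get(prev, ())
                    if s in open_leaves]
            if sibs:
                return {s: 1.0 / len(sibs) for s in sibs}
        return {l: 1.0 / len(open_leaves) for l in open_leaves}


class NoPlanningPolicy(StatelessPolicy):
    def probabilities(self, belief: BeliefState) -> Dict[int, float]:
        return {TERM: 1.0}


class RandomPlanningPolicy(StatelessPolicy):
    def __init__(self, config: EnvConfig):
        self.config = config

    def probabilities(self, belief: BeliefState) -> Dict[int, float]:
        ops = legal_operations(belief, self.config)
        return {o: 1.0 / len(ops) for o in ops}


@dataclass
class StrategySpec:
    """One generative strategy: a policy, a mixing proportion, a lapse rate."""

    name: str
    policy_factory: Callable[[EnvConfig], StatelessPolicy]
    proportion: float
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.lapse < 1:
            raise ValueError("lapse must lie in [0, 1)")


def validate_specs(specs: Sequence[StrategySpec]) -> None:
    total = sum(s.proportion for s in specs)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixing proportions must sum to 1 (got {total})")


def default_specs(lapse: float = 0.1) -> List[StrategySpec]:
    """The four benchmark strategy families, proportions normalized from
    their reported frequencies (16.7 : 31 : 22.6 : 4.3)."""
    raw = np.array([0.167, 0.31, 0.226, 0.043])
    w = raw / raw.sum()
    return [
        StrategySpec("leaf_until_max", LeafUntilMaxPolicy, float(w[0]), lapse),
        StrategySpec("sibling_leaves", SiblingLeafPolicy, float(w[1]), lapse),
        StrategySpec("no_planning", lambda c: NoPlanningPolicy(),
                     float(w[2]), lapse),
        StrategySpec("random_planning", RandomPlanningPolicy, float(w[3]), lapse),
    ]


def support_agreement(
    description_policy,
    planted_policy: StatelessPolicy,
    config: EnvConfig,
    rng: np.random.Generator,
    n_rollouts: int = 40,
) -> float:
    """Behavioral agreement between a strategy description and a planted policy.

    Rolls out the planted policy and measures, at every step, the Jaccard
    overlap between the description's currently allowed operations (its
    UNTIL/UNLESS phases tracked along the rollout) and the planted
    policy's support.  1.0 means the description denotes exactly the
    planted strategy; near 0 means unrelated behavior.
    """
    from .env import rollout  # local import to keep module deps one-way

    overlaps: List[float] = []
    for _ in range(n_rollouts):
        steps, _ = rollout(planted_policy, config, rng)
        ep = description_policy.episode()
        for j, (belief, op) in enumerate(steps):
            allowed = set(ep.probabilities(belief))
            support = set(planted_policy.probabilities(belief))
            overlaps.append(len(allowed & support) / len(allowed | support))
            nxt = steps[j + 1][0] if j + 1 < len(steps) else belief
            ep.advance(belief, op, nxt)
    return float(np.mean(overlaps))


@dataclass
class SyntheticDataset:
    trajectories: List[Trajectory]
    labels: Dict[str, str]  # participant id -> strategy name
    manifest: Dict[str, object]

    def __iter__(self):
        return iter(self.trajectories)


def _simulate_trial(
    policy: StatelessPolicy,
    lapse: float,
    config: EnvConfig,
    rng: np.random.Generator,
) -> Tuple[Tuple[Tuple[BeliefState, int], ...], Dict[int, int]]:
    gt = sample_rewards(config, rng)
    belief = BeliefState()
    steps: List[Tuple[BeliefState, int]] = []
    for _ in range(config.n_nodes + 1):
        probs = policy.probabilities(belief)
        if lapse > 0 and rng.random() < lapse:
            ops = legal_operations(belief, config)
            op = int(ops[rng.integers(len(ops))])
        else:
            ops_p = list(probs.items())
            p = np.array([q for _, q in ops_p])
            op = int(ops_p[rng.choice(len(ops_p), p=p / p.sum())][0])
        steps.append((belief, op))
        if op == TERM:
            break
        belief, _ = transition(belief, op, gt, config)
    else:
        steps.append((belief, TERM))
    return tuple(steps), gt


def generate_dataset(
    specs: Sequence[StrategySpec],
    config: EnvConfig,
    rng: np.random.Generator,
    n_participants: int = 180,
    n_trials: int = 30,
    n_train: int = 20,
) -> SyntheticDataset:
    """Simulate a labeled dataset.

    Each participant is assigned a strategy by the mixing proportions and
    plays every trial with that strategy (plus lapse noise); rewards are
    freshly sampled per trial.  The first ``n_train`` trials are labeled
    "train", the rest "test".
    """
    validate_specs(specs)
    weights = np.array([s.proportion for s in specs])
    trajectories: List[Trajectory] = []
    labels: Dict[str, str] = {}
    for p in range(n_participants):
        pid = f"p{p:03d}"
        spec = specs[int(rng.choice(len(specs), p=weights))]
        labels[pid] = spec.name
        policy = spec.policy_factory(config)
        for t in range(n_trials):
            steps, gt = _simulate_trial(policy, spec.lapse, config, rng)
            block = "train" if t < n_train else "test"
            trajectories.append(Trajectory(
                steps=steps,
                participant_id=pid,
                block=block,
                trial_index=t,
                ground_truth=tuple(gt[n] for n in config.nodes),
            ))
    manifest = {
        "n_participants": n_participants,
        "n_trials": n_trials,
        "n_train": n_train,
        "specs": [
            {"name": s.name, "proportion": s.proportion, "lapse": s.lapse}
            for s in specs
        ],
    }
    return SyntheticDataset(trajectories, labels, manifest)
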