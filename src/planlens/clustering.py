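"""Mixture-of-softmax-policies clustering of planning operations.

Each candidate strategy is a softmax policy over legal planning operations,

    pi_i(a | s, w_i) = exp(f(s,a)' w_i) / sum_{a'} exp(f(s,a')' w_i),

parameterized by weights ``w_i`` on P = 19 state-action features.  A
uniform mixture of K such policies is fitted to the observed trajectories
with soft-assignment EM; each fitted policy is then discretized to an
argmax policy (uniform over its maximizing operations) from which
demonstration rollouts are sampled for the rule-induction stage.

The EM objective is the ridge-penalized uniform-mixture log-likelihood
``sum_tau log (1/K) sum_i prod_j pi_i(a_j|s_j)``; the M-step is a weighted
multinomial-logit fit per cluster (quasi-Newton, L2 ridge), so the tracked
objective is non-decreasing up to optimizer tolerance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .env import (
    TERM,
    BeliefState,
    EnvConfig,
    StatelessPolicy,
    Trajectory,
    best_path,
    legal_operations,
    rollout,
    term_reward,
)

logger = logging.getLogger(__name__)

FEATURE_NAMES: Tuple[str, ...] = (
    "click_depth_1",
    "click_depth_2",
    "click_depth_3",
    "is_term",
    "is_leaf",
    "is_root",
    "sibling_of_previous",
    "same_branch_as_previous",
    "parent_observed",
    "child_observed",
    "term_fraction_observed",
    "term_max_observed_scaled",
    "term_min_observed_scaled",
    "term_max_reward_seen",
    "term_all_roots_observed",
    "term_all_leaves_observed",
    "term_reward_scaled",
    "term_best_path_observed_fraction",
    "bias",
)

N_FEATURES = len(FEATURE_NAMES)  # 19


def featurize(belief: BeliefState, op: int, config: EnvConfig) -> np.ndarray:
    """The 19-dimensional feature vector of one (belief, operation) pair.

    Click operations carry graph-structural indicators (depth, leaf/root,
    relation to the previously observed node, observed neighbours).  The
    belief-level descriptors (fraction observed, extreme observed values,
    whether the maximum reward has surfaced, termination reward, ...) are
    attached to the TERM operation only: a feature constant across the
    operations available in a belief cancels out of the softmax, so the
    stopping context must live on the stopping action for stop rules to be
    linearly representable.
    """
    x = np.zeros(N_FEATURES)
    obs = belief.observed
    mx = float(config.max_reward)
    if op != TERM:
        d = config.depth[op]
        if d <= 3:
            x[d - 1] = 1.0
        x[4] = 1.0 if op in config.leaves else 0.0
        x[5] = 1.0 if op in config.roots else 0.0
        prev = belief.last_click
        if prev is not None:
            x[6] = 1.0 if op in config.siblings.get(prev, ()) else 0.0
            x[7] = 1.0 if config.branch_of[op] == config.branch_of[prev] else 0.0
        x[8] = 1.0 if config.parent.get(op) in obs else 0.0
        x[9] = 1.0 if any(k in obs for k in config.children.get(op, ())) else 0.0
    else:
        x[3] = 1.0
        x[10] = len(obs) / config.n_nodes
        if obs:
            vals = list(obs.values())
            x[11] = max(vals) / mx
            x[12] = min(vals) / mx
            x[13] = 1.0 if config.max_reward in vals else 0.0
        x[14] = 1.0 if all(r in obs for r in config.roots) else 0.0
        x[15] = 1.0 if all(l in obs for l in config.leaves) else 0.0
        x[16] = term_reward(belief, config) / mx
        bp = best_path(belief, config)
        x[17] = sum(1 for n in bp if n in obs) / len(bp)
    x[18] = 1.0
    return x


@dataclass(frozen=True)
class SoftmaxPolicy(StatelessPolicy):
    """A cluster's generative click model: softmax in the 19 features."""

    weights: np.ndarray
    config: EnvConfig

    def logits(self, belief: BeliefState) -> Tuple[Tuple[int, ...], np.ndarray]:
        ops = legal_operations(belief, self.config)
        feats = np.stack([featurize(belief, o, self.config) for o in ops])
        return ops, feats @ self.weights

    def probabilities(self, belief: BeliefState) -> Dict[int, float]:
        ops, z = self.logits(belief)
        z = z - z.max()  # numerical stabilization
        p = np.exp(z)
        p /= p.sum()
        return dict(zip(ops, p))


def softmax_prob(policy: SoftmaxPolicy, belief: BeliefState, op: int) -> float:
    """pi(op | belief) under the softmax policy (max-subtracted)."""
    return policy.probabilities(belief)[op]


@dataclass(frozen=True)
class ArgmaxPolicy(StatelessPolicy):
    """Discretization of a softmax policy: uniform over its argmax set."""

    source: SoftmaxPolicy
    tie_tolerance: float = 1e-9

    def probabilities(self, belief: BeliefState) -> Dict[int, float]:
        probs = self.source.probabilities(belief)
        top = max(probs.values())
        winners = [o for o, p in probs.items() if p >= top - self.tie_tolerance]
        return {o: 1.0 / len(winners) for o in winners}


def discretize(policy: SoftmaxPolicy | ArgmaxPolicy) -> ArgmaxPolicy:
    """Uniform-over-argmax discretization; idempotent."""
    if isinstance(policy, ArgmaxPolicy):
        return policy
    return ArgmaxPolicy(policy)


# ---------------------------------------------------------------------------
# featurized data and EM
# ---------------------------------------------------------------------------

@dataclass
class FeaturizedData:
    """Padded per-step tensors for all trajectories (built once, reused)."""

    X: np.ndarray          # (n_steps, A_max, P)
    mask: np.ndarray       # (n_steps, A_max) bool
    chosen: np.ndarray     # (n_steps,) index of the taken operation
    traj_index: np.ndarray  # (n_steps,) trajectory id per step
    n_traj: int

    @classmethod
    def from_trajectories(
        cls, trajectories: Sequence[Trajectory], config: EnvConfig
    ) -> "FeaturizedData":
        rows: List[np.ndarray] = []
        chosen: List[int] = []
        tidx: List[int] = []
        a_max = config.n_nodes + 1
        feat_cache: Dict[Tuple[Tuple[int, ...], Tuple[int, ...]], np.ndarray] = {}
        mask_rows: List[np.ndarray] = []
        for t, traj in enumerate(trajectories):
            for belief, op in traj.steps:
                key = (belief.clicks, belief.values)
                cached = feat_cache.get(key)
                ops = legal_operations(belief, config)
                if cached is None:
                    F = np.zeros((a_max, N_FEATURES))
                    for k, o in enumerate(ops):
                        F[k] = featurize(belief, o, config)
                    feat_cache[key] = F
                    cached = F
                rows.append(cached)
                m = np.zeros(a_max, dtype=bool)
                m[: len(ops)] = True
                mask_rows.append(m)
                chosen.append(ops.index(op))
                tidx.append(t)
        return cls(
            X=np.asarray(rows),
            mask=np.asarray(mask_rows),
            chosen=np.asarray(chosen),
            traj_index=np.asarray(tidx),
            n_traj=len(trajectories),
        )

    def step_loglik(self, w: np.ndarray) -> np.ndarray:
        """log pi(a_j | s_j, w) for every step."""
        z = self.X @ w
        z = np.where(self.mask, z, -np.inf)
        lse = logsumexp(z, axis=1)
        return z[np.arange(len(z)), self.chosen] - lse

    def weighted_nll_and_grad(
        self, w: np.ndarray, step_weights: np.ndarray, ridge: float
    ) -> Tuple[float, np.ndarray]:
        z = self.X @ w
        zm = np.where(self.mask, z, -np.inf)
        lse = logsumexp(zm, axis=1)
        lp = zm[np.arange(len(zm)), self.chosen] - lse
        nll = -float(step_weights @ lp) + 0.5 * ridge * float(w @ w)
        p = np.exp(zm - lse[:, None])
        p[~self.mask] = 0.0
        x_chosen = self.X[np.arange(len(zm)), self.chosen]
        expected = np.einsum("sa,sap->sp", p, self.X)
        grad = -(step_weights[:, None] * (x_chosen - expected)).sum(axis=0)
        grad += ridge * w
        return nll, grad

    def traj_loglik(self, w: np.ndarray) -> np.ndarray:
        """Per-trajectory log-likelihood under one softmax policy."""
        lp = self.step_loglik(w)
        out = np.zeros(self.n_traj)
        np.add.at(out, self.traj_index, lp)
        return out


@dataclass
class ClusterModel:
    """Result of the EM fit: K softmax policies plus soft assignments."""

    policies: List[SoftmaxPolicy]
    responsibilities: np.ndarray  # (n_traj, K), rows sum to 1
    loglik_trace: List[float]
    mixing_weights: np.ndarray
    config: EnvConfig
    #: responsibilities at the assignment-unit level (== responsibilities
    #: when each trajectory is its own unit)
    group_responsibilities: np.ndarray | None = None
    group_keys: Tuple | None = None

    #: unpenalized mixture data log-likelihood at the final parameters
    data_loglik: float = float("-inf")

    @property
    def K(self) -> int:
        return len(self.policies)

    @property
    def loglik(self) -> float:
        """Final ridge-penalized EM objective (the non-decreasing trace end)."""
        return self.loglik_trace[-1]

    def hard_assignments(self) -> np.ndarray:
        return self.responsibilities.argmax(axis=1)


def _m_step(
    data: FeaturizedData,
    resp_steps: np.ndarray,
    w0: np.ndarray,
    ridge: float,
    maxiter: int,
) -> np.ndarray:
    res = minimize(
        lambda w: data.weighted_nll_and_grad(w, resp_steps, ridge),
        w0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter},
    )
    # never accept a worse point than the warm start
    f0, _ = data.weighted_nll_and_grad(w0, resp_steps, ridge)
    return res.x if res.fun <= f0 else w0


def em_fit(
    trajectories: Sequence[Trajectory],
    K: int,
    config: EnvConfig,
    rng: np.random.Generator,
    tolerance: float = 1e-3,
    change_tolerance: float = 1e-6,
    max_iter: int = 40,
    n_restarts: int = 3,
    ridge: float = 1e-4,
    m_step_maxiter: int = 12,
    data: FeaturizedData | None = None,
    groups: Sequence | None = None,
) -> ClusterModel:
    """Fit a mixture of K softmax policies with soft-assignment EM.

    Stops when the absolute objective gain drops below ``tolerance``, the
    relative gain below ``change_tolerance``, or after ``max_iter``
    iterations; the best of ``n_restarts`` random restarts is returned.
    Empty clusters are re-seeded from the worst-explained trajectory.

    ``groups`` optionally assigns each trajectory to a latent-strategy
    unit (e.g. its participant id): trajectories in one group then share a
    single cluster assignment, which is the well-specified model when a
    strategy is a stable property of a participant rather than of a single
    trial.  By default every trajectory is its own unit.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not trajectories:
        raise ValueError("trajectories must be non-empty")
    if K > len(trajectories):
        raise ValueError(f"K={K} exceeds the number of trajectories")

    n_ops_distinct = {op for t in trajectories for op in t.operations}
    if len(n_ops_distinct) == 1:
        warnings.warn("degenerate data: a single distinct planning operation",
                      stacklevel=2)

    if data is None:
        data = FeaturizedData.from_trajectories(trajectories, config)
    n_traj = data.n_traj

    # assignment units: by default every trajectory is its own unit
    if groups is None:
        group_keys = tuple(range(n_traj))
        group_of = np.arange(n_traj)
    else:
        if len(groups) != n_traj:
            raise ValueError("groups must align with trajectories")
        group_keys = tuple(dict.fromkeys(groups))
        idx = {g: i for i, g in enumerate(group_keys)}
        group_of = np.asarray([idx[g] for g in groups])
    n_groups = len(group_keys)
    if K > n_groups:
        raise ValueError(f"K={K} exceeds the number of assignment units")

    def group_loglik(W: np.ndarray) -> np.ndarray:
        ll_t = np.stack([data.traj_loglik(W[i]) for i in range(K)], axis=1)
        out = np.zeros((n_groups, K))
        np.add.at(out, group_of, ll_t)
        return out

    best: ClusterModel | None = None
    for restart in range(n_restarts):
        seed = int(rng.integers(2**31 - 1))
        sub_rng = np.random.default_rng(seed)
        logger.debug("EM restart %d seed %d", restart, seed)
        # initialize from a random hard partition: one M-step before EM
        W = np.zeros((K, N_FEATURES))
        init_assign = sub_rng.integers(K, size=n_groups)
        step_group = group_of[data.traj_index]
        for i in range(K):
            sw = (init_assign[step_group] == i).astype(float)
            if sw.sum() == 0:
                sw[:] = 1.0 / len(sw)
            W[i] = _m_step(data, sw, W[i], ridge, m_step_maxiter)
        trace: List[float] = []
        prev_obj = -np.inf
        rho = np.full(K, 1.0 / K)  # mixing weights, fitted alongside W
        resp = np.full((n_groups, K), 1.0 / K)
        for it in range(max_iter):
            # E-step
            ll = group_loglik(W)
            mix = ll + np.log(np.clip(rho, 1e-12, None))
            obj = float(logsumexp(mix, axis=1).sum())
            obj -= 0.5 * ridge * float((W * W).sum())
            trace.append(obj)
            resp = np.exp(mix - logsumexp(mix, axis=1)[:, None])
            # re-seed clusters that explain (almost) nothing
            weights = resp.sum(axis=0)
            for i in np.where(weights < 1e-3)[0]:
                worst = int(ll.max(axis=1).argmin())
                resp[worst] = 0.0
                resp[worst, i] = 1.0
            rho = resp.mean(axis=0)
            # M-step
            for i in range(K):
                sw = resp[step_group, i]
                W[i] = _m_step(data, sw, W[i], ridge, m_step_maxiter)
            if it > 0:
                gain = obj - prev_obj
                rel = abs(gain) / max(abs(prev_obj), 1.0)
                if gain < tolerance or rel < change_tolerance:
                    prev_obj = obj
                    break
            prev_obj = obj
        # final E-step at the fitted weights
        ll = group_loglik(W)
        mix = ll + np.log(np.clip(rho, 1e-12, None))
        data_ll = float(logsumexp(mix, axis=1).sum())
        obj = data_ll - 0.5 * ridge * float((W * W).sum())
        trace.append(obj)
        resp = np.exp(mix - logsumexp(mix, axis=1)[:, None])
        model = ClusterModel(
            policies=[SoftmaxPolicy(W[i].copy(), config) for i in range(K)],
            responsibilities=resp[group_of],
            loglik_trace=trace,
            mixing_weights=rho.copy(),
            config=config,
            group_responsibilities=resp,
            group_keys=group_keys,
            data_loglik=data_ll,
        )
        if best is None or model.loglik > best.loglik:
            best = model
    assert best is not None
    # polish the winning restart: one accurate M-step at the final
    # responsibilities (the loose inner M-steps are enough for EM progress
    # but leave the converged policies blunter than the data supports)
    W = np.stack([p.weights for p in best.policies])
    resp = best.group_responsibilities
    assert resp is not None
    for i in range(K):
        sw = resp[group_of, :][data.traj_index, i]
        W[i] = _m_step(data, sw, W[i], ridge, 150)
    ll = group_loglik(W)
    mix = ll + np.log(np.clip(best.mixing_weights, 1e-12, None))
    best.data_loglik = float(logsumexp(mix, axis=1).sum())
    obj = best.data_loglik - 0.5 * ridge * float((W * W).sum())
    best.loglik_trace.append(obj)
    resp = np.exp(mix - logsumexp(mix, axis=1)[:, None])
    best.policies = [SoftmaxPolicy(W[i].copy(), config) for i in range(K)]
    best.group_responsibilities = resp
    best.responsibilities = resp[group_of]
    return best


# ---------------------------------------------------------------------------
# demonstrations
# ---------------------------------------------------------------------------

@dataclass
class DemoSet:
    """Rollouts sampled from an argmax policy, with provenance.

    ``rollouts`` keeps episode boundaries (the procedural-formula extraction
    needs phase structure); ``pairs`` pools all (belief, operation) pairs.
    """

    rollouts: List[Tuple[Tuple[BeliefState, int], ...]]
    source_policy: ArgmaxPolicy
    cluster_id: int
    seed: int

    @property
    def pairs(self) -> List[Tuple[BeliefState, int]]:
        return [pair for ro in self.rollouts for pair in ro]


def sample_demos(
    argmax_policy: ArgmaxPolicy,
    config: EnvConfig,
    num_demos: int,
    rng: np.random.Generator,
    cluster_id: int = 0,
) -> DemoSet:
    """Roll out ``num_demos`` episodes of the argmax policy."""
    if num_demos < 1:
        raise ValueError("num_demos must be >= 1")
    seed = int(rng.integers(2**31 - 1))
    sub = np.random.default_rng(seed)
    rollouts = [rollout(argmax_policy, config, sub)[0] for _ in range(num_demos)]
    return DemoSet(rollouts=rollouts, source_policy=argmax_policy,
                   cluster_id=cluster_id, seed=seed)
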