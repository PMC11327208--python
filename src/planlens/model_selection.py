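"""Bayesian model selection over the number of strategies.

Each candidate model posits K clusters.  A cluster is a mixture of the
uniform policy induced by its procedural description (over the operations
the description currently allows, tracked through UNTIL/UNLESS phases) and
an *error model* — the uniform policy over the operations the description
disallows — mixed with a cluster-specific weight epsilon_i that carries a
Beta(alpha, beta) prior.  A trajectory's likelihood is the uniform mixture
over clusters of the per-step products, and models are scored by BIC
(default), AIC, or a quadrature approximation of the marginal likelihood.
Models in which any cluster could not be described are disqualified: they
are useless for understanding planning, whatever their likelihood.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import betaln, logsumexp

from .dnf2ltl import ProceduralFormula, ProceduralPolicy, allowed_operations_along
from .dsl import Predicate
from .env import EnvConfig, Trajectory, legal_operations

logger = logging.getLogger(__name__)


class NoQualifiedModelError(RuntimeError):
    """Raised when every candidate model is disqualified."""


@dataclass
class StrategyModel:
    """K described clusters with per-cluster error weights.

    For every belief the description's allowed set and its complement
    partition the legal operations; ``epsilons[i]`` is the probability mass
    the cluster diverts to the complement (the error model).
    """

    descriptions: List[Optional[ProceduralFormula]]
    predicates: Sequence[Predicate]
    config: EnvConfig
    epsilons: np.ndarray | None = None
    beta_prior: Tuple[float, float] = (1.0, 1.0)

    @property
    def K(self) -> int:
        return len(self.descriptions)

    @property
    def qualified(self) -> bool:
        return all(d is not None for d in self.descriptions)

    def policies(self) -> List[ProceduralPolicy]:
        return [
            ProceduralPolicy(d, self.predicates, self.config)
            for d in self.descriptions
            if d is not None
        ]


@dataclass
class StepProbs:
    """Per-step description / error probabilities for one (trajectory, cluster)."""

    desc: np.ndarray  # P(op) under the description-induced uniform policy
    err: np.ndarray   # P(op) under the error model (uniform over disallowed)


def step_probabilities(
    model: StrategyModel, trajectories: Sequence[Trajectory]
) -> List[List[StepProbs]]:
    """desc/err per-step arrays for every trajectory under every cluster."""
    out: List[List[StepProbs]] = []
    pols = [ProceduralPolicy(d, model.predicates, model.config)
            for d in model.descriptions if d is not None]
    if len(pols) != model.K:
        raise NoQualifiedModelError("model has undescribed clusters")
    for traj in trajectories:
        per_cluster: List[StepProbs] = []
        for pol in pols:
            allowed_sets = allowed_operations_along(pol, traj.steps)
            desc = np.zeros(len(traj.steps))
            err = np.zeros(len(traj.steps))
            for j, ((belief, op), allowed) in enumerate(
                    zip(traj.steps, allowed_sets)):
                legal = legal_operations(belief, model.config)
                disallowed = [o for o in legal if o not in allowed]
                if op in allowed:
                    desc[j] = 1.0 / len(allowed)
                elif disallowed:
                    err[j] = 1.0 / len(disallowed)
            per_cluster.append(StepProbs(desc, err))
        out.append(per_cluster)
    return out


def _cluster_logliks(
    probs: List[List[StepProbs]], epsilons: np.ndarray
) -> np.ndarray:
    """log P_i(tau; eps_i) for every trajectory x cluster: the log of the
    per-step error-mixture product."""
    n, K = len(probs), len(epsilons)
    out = np.full((n, K), -np.inf)
    for t in range(n):
        for i in range(K):
            sp = probs[t][i]
            per_step = epsilons[i] * sp.err + (1.0 - epsilons[i]) * sp.desc
            with np.errstate(divide="ignore"):
                out[t, i] = float(np.log(per_step).sum())
    return out


def trajectory_likelihood(
    traj: Trajectory, model: StrategyModel
) -> float:
    """P(tau | eps): uniform mixture over clusters of the per-step products."""
    eps = model.epsilons
    if eps is None:
        raise ValueError("fit epsilons first")
    probs = step_probabilities(model, [traj])
    ll = _cluster_logliks(probs, eps)[0]
    return float(np.exp(logsumexp(ll - math.log(model.K))))


def _log_posterior(probs, epsilons, a, b) -> float:
    ll = _cluster_logliks(probs, epsilons)
    K = len(epsilons)
    data_ll = float(logsumexp(ll - math.log(K), axis=1).sum())
    prior = float(np.sum((a - 1) * np.log(np.clip(epsilons, 1e-12, None))
                         + (b - 1) * np.log(np.clip(1 - epsilons, 1e-12, None))))
    return data_ll + prior


def fit_epsilons(
    trajectories: Sequence[Trajectory],
    model: StrategyModel,
    grid_size: int = 101,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> np.ndarray:
    """Per-cluster MAP estimate of epsilon under the Beta prior.

    EM over the latent cluster assignment with a grid M-step per cluster
    (the per-cluster objective is one-dimensional and bounded in [0, 1]).
    The optimized penalized objective is non-decreasing across iterations.
    """
    if not trajectories:
        raise ValueError("data must be non-empty")
    a, b = model.beta_prior
    probs = step_probabilities(model, trajectories)
    K = model.K
    eps = np.full(K, 0.1)
    grid = np.linspace(1e-4, 1 - 1e-4, grid_size)
    prev = -np.inf
    for _ in range(max_iter):
        ll = _cluster_logliks(probs, eps)
        log_resp = ll - logsumexp(ll, axis=1)[:, None]
        resp = np.exp(log_resp)
        for i in range(K):
            # weighted per-cluster log-likelihood on the epsilon grid
            scores = np.zeros_like(grid)
            for t, per_cluster in enumerate(probs):
                sp = per_cluster[i]
                per_step = (grid[:, None] * sp.err[None, :]
                            + (1 - grid)[:, None] * sp.desc[None, :])
                with np.errstate(divide="ignore"):
                    scores += resp[t, i] * np.log(per_step).sum(axis=1)
            scores += (a - 1) * np.log(grid) + (b - 1) * np.log(1 - grid)
            eps[i] = float(grid[int(np.argmax(scores))])
        cur = _log_posterior(probs, eps, a, b)
        if cur - prev < tol:
            break
        prev = cur
    model.epsilons = eps
    return eps


@dataclass
class ScoreResult:
    """Higher-is-better score of one model under one criterion."""

    K: int
    criterion: str
    value: float
    loglik: float
    n_operations: int
    disqualified: bool = False


def score(
    model: StrategyModel,
    trajectories: Sequence[Trajectory],
    criterion: str = "bic",
    quadrature_points: int = 31,
) -> ScoreResult:
    """Score a fitted model; disqualified models get value -inf and a flag.

    BIC = -2 logL + p log n and AIC = -2 logL + 2 p with p = K free epsilon
    parameters and n = total planning operations (operations are the
    likelihood's atomic terms); both are reported negated so that higher is
    better under every criterion.  The marginal likelihood integrates each
    cluster's epsilon over its Beta prior on a fixed grid.
    """
    n_ops = sum(len(t) for t in trajectories)
    if not model.qualified:
        return ScoreResult(model.K, criterion, -math.inf, -math.inf,
                           n_ops, disqualified=True)
    if model.epsilons is None:
        fit_epsilons(trajectories, model)
    probs = step_probabilities(model, trajectories)
    ll = _cluster_logliks(probs, model.epsilons)
    loglik = float(logsumexp(ll - math.log(model.K), axis=1).sum())
    p = model.K
    if criterion == "bic":
        value = -(-2.0 * loglik + p * math.log(max(n_ops, 1)))
    elif criterion == "aic":
        value = -(-2.0 * loglik + 2.0 * p)
    elif criterion == "marginal":
        a, b = model.beta_prior
        grid = np.linspace(1e-4, 1 - 1e-4, quadrature_points)
        logw = ((a - 1) * np.log(grid) + (b - 1) * np.log(1 - grid)
                - betaln(a, b))
        logw -= logsumexp(logw)  # normalized quadrature weights
        value = 0.0
        for t, per_cluster in enumerate(probs):
            per_cluster_ml = np.empty(model.K)
            for i in range(model.K):
                sp = per_cluster[i]
                per_step = (grid[:, None] * sp.err[None, :]
                            + (1 - grid)[:, None] * sp.desc[None, :])
                with np.errstate(divide="ignore"):
                    g = np.log(per_step).sum(axis=1)
                per_cluster_ml[i] = logsumexp(g + logw)
            value += float(logsumexp(per_cluster_ml - math.log(model.K)))
    else:
        raise ValueError(f"unknown criterion '{criterion}'")
    return ScoreResult(model.K, criterion, value, loglik, n_ops)


@dataclass
class SelectionResult:
    scores: List[ScoreResult]
    winner: ScoreResult

    @property
    def best_K(self) -> int:
        return self.winner.K


def select_best(results: Sequence[ScoreResult]) -> SelectionResult:
    """Argmax over qualified scores; ties resolved toward smaller K."""
    qualified = [r for r in results if not r.disqualified]
    if not qualified:
        raise NoQualifiedModelError(
            "every candidate model had undescribed clusters")
    winner = max(qualified, key=lambda r: (r.value, -r.K))
    return SelectionResult(scores=list(results), winner=winner)
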