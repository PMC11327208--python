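"""Aggregation across pipeline runs and the reported reliability statistics.

A single run of the discovery pipeline is stochastic; the method therefore
repeats it (10 runs by default), matches strategies across runs by
canonical procedural-formula equality, and keeps a strategy only if it was
discovered in at least a threshold number of runs (the majority heuristic;
the threshold itself is calibrated by cross-validation over 10-run subsets
of a larger run pool).  This module also computes the signal-detection
metrics of a discovered strategy set against a ground truth, the
stability/variability of the aggregated output, and the per-strategy fit
statistics FR / FCF / FPO / FON.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .dnf2ltl import ProceduralFormula, ProceduralPolicy, allowed_operations_along
from .clustering import ArgmaxPolicy
from .dsl import Predicate
from .env import (
    BeliefState,
    EnvConfig,
    Trajectory,
    legal_operations,
    rollout,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# strategies across runs
# ---------------------------------------------------------------------------

@dataclass
class DiscoveredStrategy:
    """One strategy as reported by one run."""

    formula: ProceduralFormula
    description: str
    run_id: int
    cluster_id: int
    statistics: Dict[str, float] = field(default_factory=dict)

    @property
    def key(self) -> str:
        return self.formula.canonical()


@dataclass
class RunOutput:
    """The selected model of one pipeline run."""

    run_id: int
    K: int
    strategies: List[DiscoveredStrategy]

    def keys(self) -> Set[str]:
        return {s.key for s in self.strategies}


@dataclass
class StrategyClass:
    """An identity class of strategies matched across runs."""

    key: str
    members: List[DiscoveredStrategy]

    @property
    def multiplicity(self) -> int:
        return len({m.run_id for m in self.members})


def _jaccard(a: Set[str], b: Set[str]) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def match_strategies(
    run_outputs: Sequence[RunOutput],
    near_match_threshold: float = 0.8,
) -> List[StrategyClass]:
    """Group strategies by canonical formula-string equality.

    Pairs of distinct classes whose literal sets overlap with Jaccard
    similarity >= ``near_match_threshold`` are logged as near-matches for
    manual review (they remain separate classes).
    """
    if len(run_outputs) < 2:
        raise ValueError("matching needs at least 2 runs")
    classes: Dict[str, StrategyClass] = {}
    for out in run_outputs:
        for s in out.strategies:
            cls = classes.setdefault(s.key, StrategyClass(s.key, []))
            cls.members.append(s)
    result = sorted(classes.values(), key=lambda c: (-c.multiplicity, c.key))
    for a, b in itertools.combinations(result, 2):
        la = a.members[0].formula.predicate_names()
        lb = b.members[0].formula.predicate_names()
        if _jaccard(la, lb) >= near_match_threshold:
            logger.info("near-match (review): %r vs %r", a.key, b.key)
    return result


def majority_select(
    classes: Sequence[StrategyClass], n_runs: int, threshold: int
) -> List[StrategyClass]:
    """Keep classes discovered in at least ``threshold`` of ``n_runs`` runs."""
    if not 1 <= threshold <= n_runs:
        raise ValueError("threshold must lie in [1, n_runs]")
    return [c for c in classes if c.multiplicity >= threshold]


# ---------------------------------------------------------------------------
# detection metrics
# ---------------------------------------------------------------------------

@dataclass
class DetectionCounts:
    """Confusion counts of a discovered set B against ground truth G within
    a candidate universe S."""

    universe: FrozenSet[str]
    ground_truth: FrozenSet[str]
    discovered: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.ground_truth <= self.universe:
            raise ValueError("ground truth must be a subset of the universe")
        if not self.discovered <= self.universe:
            raise ValueError("discovered set must be a subset of the universe")

    @property
    def tp(self) -> int:
        return len(self.discovered & self.ground_truth)

    @property
    def fp(self) -> int:
        return len(self.discovered - self.ground_truth)

    @property
    def fn(self) -> int:
        return len(self.ground_truth - self.discovered)

    @property
    def tn(self) -> int:
        return len(self.universe) - self.tp - self.fp - self.fn


@dataclass
class DetectionMetrics:
    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    undefined: Tuple[str, ...] = ()


def detection_metrics(counts: DetectionCounts) -> DetectionMetrics:
    """accuracy, precision, recall and F1 of the discovered set.

    accuracy = (TP + TN) / |S|; precision = TP / |B|; recall = TP / |G|;
    F1 = 2 * precision * recall / (precision + recall).  Division-by-zero
    cases are reported as None with a flag naming the metric.
    """
    undefined: List[str] = []
    n_s = len(counts.universe)
    accuracy = (counts.tp + counts.tn) / n_s if n_s else None
    if n_s == 0:
        undefined.append("accuracy")
    n_b = len(counts.discovered)
    n_g = len(counts.ground_truth)
    precision = counts.tp / n_b if n_b else None
    if not n_b:
        undefined.append("precision")
    recall = counts.tp / n_g if n_g else None
    if not n_g:
        undefined.append("recall")
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision is not None and recall is not None:
        f1 = 0.0
    else:
        f1 = None
        undefined.append("f1")
    return DetectionMetrics(accuracy, precision, recall, f1, tuple(undefined))


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------

def count_run_subsets(pool_size: int, subset_size: int = 10) -> int:
    """Number of distinct ``subset_size``-run subsets of the pool."""
    return math.comb(pool_size, subset_size)


def enumerate_run_subsets(
    pool_size: int, subset_size: int = 10
) -> "itertools.combinations":
    return itertools.combinations(range(pool_size), subset_size)


@dataclass
class CalibrationResult:
    threshold: int
    train_accuracy: float
    test_metrics: DetectionMetrics
    n_subsets: int


def calibrate_threshold(
    run_pool: Sequence[RunOutput],
    ground_truth: Set[str],
    rng: np.random.Generator,
    subset_size: int = 10,
    train_fraction: float = 0.7,
    max_subsets: Optional[int] = None,
) -> CalibrationResult:
    """Cross-validate the majority threshold over 10-run subsets of the pool.

    All ``C(pool, 10)`` subsets are enumerated (optionally subsampled,
    seeded, via ``max_subsets``), split 70/30, and the threshold maximizing
    mean detection accuracy on the training subsets is returned, with test
    metrics at that threshold.  Ties go to the largest threshold (the most
    conservative noise filter among equally accurate ones).
    """
    if not ground_truth:
        raise ValueError("ground truth must be non-empty")
    n = len(run_pool)
    if n < subset_size:
        raise ValueError("run pool smaller than the subset size")

    keys = sorted({k for out in run_pool for k in out.keys()} | ground_truth)
    key_idx = {k: i for i, k in enumerate(keys)}
    runs_matrix = np.zeros((n, len(keys)), dtype=np.int16)
    for i, out in enumerate(run_pool):
        for k in out.keys():
            runs_matrix[i, key_idx[k]] = 1
    gt_vec = np.array([k in ground_truth for k in keys])

    combos = np.array(list(enumerate_run_subsets(n, subset_size)), dtype=np.int16)
    n_subsets = len(combos)
    if max_subsets is not None and n_subsets > max_subsets:
        pick = rng.choice(n_subsets, size=max_subsets, replace=False)
        combos = combos[np.sort(pick)]
        n_subsets = max_subsets

    perm = rng.permutation(n_subsets)
    n_train = int(round(train_fraction * n_subsets))
    train_idx, test_idx = perm[:n_train], perm[n_train:]

    # multiplicity of every strategy in every subset
    mult = runs_matrix[combos].sum(axis=1)  # (n_subsets, n_keys)
    n_s = len(keys)

    def accuracies(threshold: int, idx: np.ndarray) -> np.ndarray:
        B = mult[idx] >= threshold
        tp = (B & gt_vec).sum(axis=1)
        tn = (~B & ~gt_vec).sum(axis=1)
        return (tp + tn) / n_s

    best_t, best_acc = 1, -1.0
    for t in range(1, subset_size + 1):
        acc = float(accuracies(t, train_idx).mean())
        if acc >= best_acc:  # ties -> largest threshold
            best_t, best_acc = t, acc

    # test metrics at the calibrated threshold, averaged over test subsets
    B_test = mult[test_idx] >= best_t
    tp = (B_test & gt_vec).sum(axis=1).astype(float)
    nb = B_test.sum(axis=1).astype(float)
    ng = float(gt_vec.sum())
    tn = (~B_test & ~gt_vec).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(nb > 0, tp / nb, np.nan)
        rec = tp / ng
        f1 = np.where((prec + rec) > 0, 2 * prec * rec / (prec + rec), 0.0)
    test = DetectionMetrics(
        accuracy=float(((tp + tn) / n_s).mean()),
        precision=float(np.nanmean(prec)),
        recall=float(np.mean(rec)),
        f1=float(np.nanmean(f1)),
    )
    return CalibrationResult(best_t, best_acc, test, len(combos))


# ---------------------------------------------------------------------------
# stability and variability
# ---------------------------------------------------------------------------

def stability_variability(
    outputs_pool: Sequence[Set[str]],
) -> Tuple[float, float]:
    """Stability: fraction of outputs equal (as sets) to the modal output.
    Variability: mean symmetric-difference size over unordered pairs of
    *differing* outputs (0 when all outputs agree)."""
    if len(outputs_pool) < 2:
        raise ValueError("need at least 2 aggregated outputs")
    frozen = [frozenset(o) for o in outputs_pool]
    modal, modal_count = Counter(frozen).most_common(1)[0]
    stability = modal_count / len(frozen)
    diffs = [
        len(a ^ b)
        for a, b in itertools.combinations(frozen, 2)
        if a != b
    ]
    variability = float(np.mean(diffs)) if diffs else 0.0
    return stability, variability


def write_final_report(
    classes: Sequence[StrategyClass],
    n_runs: int,
    txt_path,
    json_path,
) -> None:
    """Write the aggregated strategy report as text plus machine-readable JSON.

    One block per strategy class: its canonical formula, the description
    text of a representative member, the number of runs it appeared in,
    and the averaged FR/FCF/FON/FPO statistics of its members.
    """
    import json

    blocks = []
    records = []
    for c in classes:
        stats_keys = sorted({k for m in c.members for k in m.statistics})
        avg = {k: float(np.mean([m.statistics[k] for m in c.members
                                 if k in m.statistics]))
               for k in stats_keys}
        rep = c.members[0]
        stat_line = " ".join(f"{k}={v:.3f}" for k, v in avg.items())
        blocks.append("\n".join(filter(None, [
            f"STRATEGY (in {c.multiplicity}/{n_runs} runs)",
            c.key,
            rep.description,
            stat_line,
        ])))
        records.append({
            "formula": c.key,
            "description": rep.description,
            "runs": c.multiplicity,
            "n_runs": n_runs,
            "statistics": avg,
        })
    Path(txt_path).write_text("\n\n".join(blocks) + "\n", encoding="utf-8")
    Path(json_path).write_text(json.dumps(records, indent=2),
                               encoding="utf-8")


# ---------------------------------------------------------------------------
# fit statistics (FR / FCF / FPO / FON)
# ---------------------------------------------------------------------------

@dataclass
class ClusterData:
    """What the fit statistics need to know about one described cluster."""

    member_trajectories: List[Trajectory]
    softmax_argmax: ArgmaxPolicy
    description: ProceduralFormula
    n_total_trajectories: int
    epsilon: float = 0.0


@dataclass
class FitStatistics:
    FR: float
    FCF: float
    FPO: float
    FON: float


def fit_statistics(
    cluster: ClusterData,
    predicates: Sequence[Predicate],
    config: EnvConfig,
    rng: np.random.Generator,
    n_demos: int = 10_000,
) -> FitStatistics:
    """Per-strategy statistics of one described cluster.

    FR: fraction of all trajectories whose maximum responsibility falls in
    this cluster (trial-level).  FCF: mean of (i) the fraction of
    description-policy demonstration operations receiving positive
    probability under the cluster's argmax softmax policy and (ii) the
    converse.  FPO: ratio of the mean per-operation probability of the
    cluster members under the epsilon-mixture to the same quantity for
    operations drawn from the description's policy *at the same beliefs*
    (the paired evaluation makes a cluster described by the random/True
    formula score exactly 1).  FON: fraction of member operations the
    description allows in its currently active step.
    """
    if not cluster.member_trajectories:
        raise ValueError("cluster is non-empty by precondition")
    pol = ProceduralPolicy(cluster.description, predicates, config)
    eps = cluster.epsilon

    FR = len(cluster.member_trajectories) / cluster.n_total_trajectories

    # --- FCF ---------------------------------------------------------------
    n_roll = max(1, n_demos // (config.n_nodes + 1))
    agree_fd = []  # formula demos vs softmax cluster
    for _ in range(n_roll):
        steps, _ = rollout(pol, config, rng)
        for belief, op in steps:
            agree_fd.append(
                cluster.softmax_argmax.probabilities(belief).get(op, 0.0) > 0)
            if len(agree_fd) >= n_demos:
                break
        if len(agree_fd) >= n_demos:
            break
    agree_df = []  # softmax demos vs formula
    for _ in range(n_roll):
        steps, _ = rollout(cluster.softmax_argmax, config, rng)
        allowed = allowed_operations_along(pol, steps)
        for (belief, op), ok in zip(steps, allowed):
            agree_df.append(op in ok)
            if len(agree_df) >= n_demos:
                break
        if len(agree_df) >= n_demos:
            break
    FCF = 0.5 * (float(np.mean(agree_fd)) + float(np.mean(agree_df)))

    # --- FPO / FON ---------------------------------------------------------
    member_probs: List[float] = []
    sampled_probs: List[float] = []
    allowed_flags: List[bool] = []

    def mixture_prob(belief: BeliefState, op: int,
                     allowed: Tuple[int, ...]) -> float:
        legal = legal_operations(belief, config)
        disallowed = [o for o in legal if o not in allowed]
        if op in allowed:
            return (1 - eps) / len(allowed)
        return eps / len(disallowed) if disallowed else 0.0

    for traj in cluster.member_trajectories:
        allowed_sets = allowed_operations_along(pol, traj.steps)
        for (belief, op), allowed in zip(traj.steps, allowed_sets):
            member_probs.append(mixture_prob(belief, op, allowed))
            allowed_flags.append(op in allowed)
            # paired draw from the description policy at the same belief
            draw = list(allowed)
            alt = draw[int(rng.integers(len(draw)))]
            sampled_probs.append(mixture_prob(belief, alt, allowed))

    denom = float(np.mean(sampled_probs))
    FPO = float(np.mean(member_probs)) / denom if denom > 0 else 0.0
    FON = float(np.mean(allowed_flags))
    return FitStatistics(FR=FR, FCF=FCF, FPO=FPO, FON=FON)
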