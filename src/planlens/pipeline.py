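"""End-to-end pipeline: cluster -> describe -> temporalize -> translate ->
select, for a range of cluster counts, with fully seeded randomness.

One run evaluates every K from ``begin`` to ``max_num_strategies``: fits
the softmax mixture, describes each cluster's argmax demonstrations as a
DNF, converts it to a procedural formula, prunes it against the cluster's
human operations, renders it in natural language, scores the resulting
error-mixture model under the chosen criterion, and selects the best
qualified K.  Outputs mirror the reference interface: a
``BEST_strategies_<name>_<max>_<num_p>_<demos>_run<run>`` text file plus a
JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from . import io as plio
from .aggregate import ClusterData, DiscoveredStrategy, FitStatistics, RunOutput, fit_statistics
from .clustering import ClusterModel, FeaturizedData, discretize, em_fit, sample_demos
from .dnf2ltl import (
    ConversionError,
    ProceduralFormula,
    condition_pool,
    dnf_to_procedural,
    prune,
)
from .dnf_learning import InterpretParams, InterpretResult, interpret
from .dsl import Predicate, default_vocabulary
from .env import TERM, EnvConfig, Trajectory, default_config
from .model_selection import (
    NoQualifiedModelError,
    ScoreResult,
    StrategyModel,
    fit_epsilons,
    score,
    select_best,
)
from .translate import TranslationDictionary, default_dictionary, render

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline invocation, mirroring the reference CLI parameters."""

    run: int = 1
    experiment_id: str = "synthetic"
    max_num_strategies: int = 4
    begin: int = 1
    num_participants: int = 0       # 0 = all
    expert_reward: float = 39.97
    num_demos: int = 32
    block: Optional[str] = None
    criterion: str = "bic"
    seed: int = 0
    data_path: Optional[str] = None
    out_dir: str = "interprets_procedure"
    # search knobs
    interpret_depth: int = 6
    max_divergence: float = 0.2
    num_rollouts: int = 32
    num_ai_clusters: int = 3
    em_restarts: int = 2
    em_max_iter: int = 30
    fit_stat_demos: int = 500
    #: share a participant's trials in one cluster assignment (a strategy is
    #: modeled as a stable property of a participant)
    group_by_participant: bool = True

    def __post_init__(self) -> None:
        if self.begin > self.max_num_strategies:
            raise ValueError("begin must be <= max_num_strategies")
        if self.expert_reward <= 0:
            raise ValueError("expert_reward must be > 0")


@dataclass
class DescribedCluster:
    cluster_id: int
    formula: Optional[ProceduralFormula]
    text: Optional[str]
    interpret: InterpretResult
    statistics: Optional[FitStatistics] = None


@dataclass
class PerK:
    K: int
    clusters: List[DescribedCluster]
    model: Optional[StrategyModel]
    score: Optional[ScoreResult]
    error: Optional[str] = None


@dataclass
class RunResult:
    config: RunConfig
    per_k: List[PerK]
    selected: PerK
    output: RunOutput
    best_file: Optional[Path] = None


def describe_cluster(
    cluster_model: ClusterModel,
    cluster_id: int,
    members: Sequence[Trajectory],
    vocabulary: Sequence[Predicate],
    params: InterpretParams,
    config: EnvConfig,
    num_demos: int,
    rng: np.random.Generator,
) -> DescribedCluster:
    """Demonstrate, describe, temporalize and prune one cluster."""
    argmax = discretize(cluster_model.policies[cluster_id])
    demos = sample_demos(argmax, config, num_demos, rng, cluster_id=cluster_id)
    result = interpret(demos, vocabulary, params, config, rng)
    if not result.success:
        return DescribedCluster(cluster_id, None, None, result)
    pool = condition_pool(vocabulary)
    try:
        procedural = dnf_to_procedural(
            result.formula,
            [list(r) for r in demos.rollouts],
            pool, vocabulary, config)
    except ConversionError:
        # retain only the demonstrations the formula covers
        registry = {p.name: p for p in vocabulary}
        covered = [
            [(b, o) for b, o in r
             if o == TERM or result.formula.satisfies(b, o, config, registry)]
            for r in demos.rollouts
        ]
        covered = [r for r in covered if r]
        procedural = dnf_to_procedural(result.formula, covered, pool,
                                       vocabulary, config)
    if members:
        procedural = prune(procedural, [list(t.steps) for t in members],
                           vocabulary, config)
    return DescribedCluster(cluster_id, procedural, None, result)


def run_pipeline(
    config: RunConfig,
    trajectories: Optional[Sequence[Trajectory]] = None,
    env: Optional[EnvConfig] = None,
    vocabulary: Optional[Sequence[Predicate]] = None,
    dictionary: Optional[TranslationDictionary] = None,
    write_files: bool = True,
) -> RunResult:
    """Execute one full run; every source of randomness flows from the seed.

    Per-K failures are recorded; the run aborts only if every K fails.
    """
    env = env or default_config()
    if trajectories is None:
        if config.data_path is None:
            raise ValueError("either trajectories or data_path is required")
        trajectories = plio.read_traces(
            config.data_path, env, block=config.block,
            num_participants=config.num_participants)
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("no trajectories to analyze")
    vocabulary = vocabulary or default_vocabulary(env)
    dictionary = dictionary or default_dictionary()
    rng = np.random.default_rng(config.seed + 977 * config.run)
    params = InterpretParams(
        depth=config.interpret_depth,
        max_divergence=config.max_divergence,
        num_rollouts=config.num_rollouts,
        num_ai_clusters=config.num_ai_clusters,
        expert_reward=config.expert_reward,
    )

    data = FeaturizedData.from_trajectories(trajectories, env)
    groups = ([t.participant_id for t in trajectories]
              if config.group_by_participant else None)
    per_k: List[PerK] = []
    for K in range(config.begin, config.max_num_strategies + 1):
        sub_seed = int(rng.integers(2**31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        logger.info("run %d: K=%d (seed %d)", config.run, K, sub_seed)
        try:
            cm = em_fit(trajectories, K, env, sub_rng,
                        n_restarts=config.em_restarts,
                        max_iter=config.em_max_iter, data=data,
                        groups=groups)
            hard = cm.hard_assignments()
            clusters: List[DescribedCluster] = []
            for i in range(K):
                members = [t for t, h in zip(trajectories, hard) if h == i]
                clusters.append(describe_cluster(
                    cm, i, members, vocabulary, params, env,
                    config.num_demos, sub_rng))
            model = StrategyModel(
                descriptions=[c.formula for c in clusters],
                predicates=vocabulary, config=env)
            if model.qualified:
                fit_epsilons(trajectories, model)
            sc = score(model, trajectories, criterion=config.criterion)
            # per-cluster text and statistics
            for i, c in enumerate(clusters):
                if c.formula is None:
                    continue
                c.text = render(c.formula, dictionary, env)
                members = [t for t, h in zip(trajectories, hard) if h == i]
                if members and model.qualified:
                    cd = ClusterData(
                        member_trajectories=members,
                        softmax_argmax=discretize(cm.policies[i]),
                        description=c.formula,
                        n_total_trajectories=len(trajectories),
                        epsilon=float(model.epsilons[i]),
                    )
                    c.statistics = fit_statistics(
                        cd, vocabulary, env, sub_rng,
                        n_demos=config.fit_stat_demos)
            per_k.append(PerK(K, clusters, model, sc))
        except Exception as exc:  # per-K failures are data, not fatal
            logger.exception("run %d: K=%d failed", config.run, K)
            per_k.append(PerK(K, [], None, None, error=str(exc)))

    scored = [p.score for p in per_k if p.score is not None]
    if not scored:
        raise RuntimeError("every K failed; see the per-K errors")
    selection = select_best(scored)
    selected = next(p for p in per_k
                    if p.score is not None and p.score.K == selection.best_K)

    strategies = [
        DiscoveredStrategy(
            formula=c.formula, description=c.text or "",
            run_id=config.run, cluster_id=c.cluster_id,
            statistics=dataclasses.asdict(c.statistics)
            if c.statistics else {},
        )
        for c in selected.clusters if c.formula is not None
    ]
    output = RunOutput(run_id=config.run, K=selected.K, strategies=strategies)

    best_file: Optional[Path] = None
    if write_files:
        best_file = _write_outputs(config, per_k, selected, output)
    return RunResult(config, per_k, selected, output, best_file)


def _best_filename(config: RunConfig) -> str:
    return (f"BEST_strategies_{config.experiment_id}_"
            f"{config.max_num_strategies}_{config.num_participants}_"
            f"{config.num_demos}_run{config.run}")


def _write_outputs(config: RunConfig, per_k: List[PerK], selected: PerK,
                   output: RunOutput) -> Path:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    best = out_dir / (_best_filename(config) + ".txt")
    blocks: List[str] = []
    for c in selected.clusters:
        if c.formula is None:
            blocks.append(f"CLUSTER {c.cluster_id}: <no description found>")
            continue
        stats = c.statistics
        stat_line = (
            f"FR={stats.FR:.3f} FCF={stats.FCF:.3f} "
            f"FON={stats.FON:.3f} FPO={stats.FPO:.3f}"
            if stats else "")
        blocks.append("\n".join(filter(None, [
            f"CLUSTER {c.cluster_id}",
            c.formula.canonical(),
            c.text or "",
            stat_line,
        ])))
    best.write_text("\n\n".join(blocks) + "\n", encoding="utf-8")

    manifest = {
        "run": config.run,
        "experiment_id": config.experiment_id,
        "seed": config.seed,
        "criterion": config.criterion,
        "selected_K": selected.K,
        "scores": [
            {"K": p.K,
             "score": None if p.score is None else p.score.value,
             "loglik": None if p.score is None else p.score.loglik,
             "disqualified": p.score.disqualified if p.score else True,
             "error": p.error}
            for p in per_k
        ],
        "strategies": [
            {"cluster_id": s.cluster_id,
             "formula": s.formula.canonical(),
             "description": s.description,
             "statistics": s.statistics}
            for s in output.strategies
        ],
    }
    (out_dir / (_best_filename(config) + ".json")).write_text(
        json.dumps(manifest, indent=2), encoding="utf-8")
    # per-K score table as CSV
    import pandas as pd

    pd.DataFrame([
        {"K": p.K,
         "score": None if p.score is None else p.score.value,
         "loglik": None if p.score is None else p.score.loglik,
         "disqualified": p.score.disqualified if p.score else True}
        for p in per_k
    ]).to_csv(out_dir / (_best_filename(config) + "_scores.csv"), index=False)
    return best
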