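"""Readers and writers for process-tracing tables and environment configs.

The CSV dialect is UTF-8, comma-separated, with header
``participant_id,block,trial_index,clicks,rewards``: ``clicks`` is the
space-separated ordered list of clicked node ids (1-based; TERM is
implicit at the end of every trial) and ``rewards`` the space-separated
ground-truth rewards in node-id order.  Strategy labels travel in a
sidecar CSV (``participant_id,strategy``).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .env import TERM, BeliefState, EnvConfig, Trajectory
from .synthetic_data import SyntheticDataset

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ("participant_id", "block", "trial_index", "clicks", "rewards")


class TraceFormatError(ValueError):
    pass


def write_traces(trajectories: Sequence[Trajectory], path: str | Path) -> None:
    rows = []
    for t in trajectories:
        clicks = " ".join(str(op) for op in t.operations if op != TERM)
        rewards = " ".join(str(v) for v in t.ground_truth)
        rows.append({
            "participant_id": t.participant_id,
            "block": t.block,
            "trial_index": t.trial_index,
            "clicks": clicks,
            "rewards": rewards,
        })
    pd.DataFrame(rows, columns=list(TRACE_COLUMNS)).to_csv(path, index=False)


def write_labels(labels: Dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(labels.items()), columns=["participant_id", "strategy"]
    ).to_csv(path, index=False)


def read_labels(path: str | Path) -> Dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df["participant_id"], df["strategy"]))


def write_dataset(dataset: SyntheticDataset, traces_path: str | Path,
                  labels_path: str | Path) -> None:
    write_traces(dataset.trajectories, traces_path)
    write_labels(dataset.labels, labels_path)


def _rebuild_trajectory(
    row_number: int,
    participant_id: str,
    block: str,
    trial_index: int,
    clicks: List[int],
    rewards: List[int],
    config: EnvConfig,
) -> Trajectory:
    if len(rewards) != config.n_nodes:
        raise TraceFormatError(
            f"row {row_number}: expected {config.n_nodes} rewards, "
            f"got {len(rewards)}")
    gt = dict(zip(config.nodes, rewards))
    belief = BeliefState()
    steps: List[Tuple[BeliefState, int]] = []
    for c in clicks:
        if c not in config.depth:
            raise TraceFormatError(f"row {row_number}: unknown node id {c}")
        if belief.is_observed(c):
            logger.warning(
                "row %d: dropping duplicate click on node %d", row_number, c)
            continue
        steps.append((belief, c))
        belief = belief.observe(c, gt[c])
    steps.append((belief, TERM))
    return Trajectory(
        steps=tuple(steps),
        participant_id=participant_id,
        block=block,
        trial_index=trial_index,
        ground_truth=tuple(rewards),
    )


def read_traces(
    path: str | Path,
    config: EnvConfig,
    block: Optional[str] = None,
    num_participants: int = 0,
) -> List[Trajectory]:
    """Load trajectories, reconstructing belief states from click order.

    ``block`` filters to one experimental block; ``num_participants`` > 0
    truncates to the first that many participants (0 loads all).  Duplicate
    clicks are dropped with a logged warning; malformed rows raise
    :class:`TraceFormatError` with the row number.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "block": str,
                                  "clicks": str, "rewards": str})
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise TraceFormatError(f"missing columns: {sorted(missing)}")
    if block is not None:
        df = df[df["block"] == block]
    if num_participants > 0:
        keep = list(dict.fromkeys(df["participant_id"]))[:num_participants]
        df = df[df["participant_id"].isin(keep)]
    out: List[Trajectory] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        try:
            clicks = ([int(x) for x in str(row.clicks).split()]
                      if isinstance(row.clicks, str) and row.clicks.strip()
                      else [])
            rewards = [int(x) for x in str(row.rewards).split()]
            trial_index = int(row.trial_index)
        except (TypeError, ValueError) as exc:
            raise TraceFormatError(f"row {row_number}: malformed row ({exc})")
        out.append(_rebuild_trajectory(
            row_number, row.participant_id, row.block, trial_index,
            clicks, rewards, config))
    return out


def write_cluster_model(model, trajectories: Sequence[Trajectory],
                        prefix: str | Path) -> None:
    """Persist a fitted cluster model: per-cluster softmax weights
    (``<prefix>_weights.csv``) and per-trajectory hard assignments with
    responsibilities (``<prefix>_assignments.csv``)."""
    from .clustering import FEATURE_NAMES

    prefix = Path(prefix)
    pd.DataFrame(
        [p.weights for p in model.policies],
        columns=list(FEATURE_NAMES),
    ).rename_axis("cluster").to_csv(f"{prefix}_weights.csv")
    hard = model.hard_assignments()
    rows = []
    for i, t in enumerate(trajectories):
        row = {"participant_id": t.participant_id, "block": t.block,
               "trial_index": t.trial_index, "cluster": int(hard[i])}
        for k in range(model.K):
            row[f"resp_{k}"] = float(model.responsibilities[i, k])
        rows.append(row)
    pd.DataFrame(rows).to_csv(f"{prefix}_assignments.csv", index=False)


def load_env_config(path: str | Path) -> EnvConfig:
    """Environment config from YAML/JSON: ``layout`` (child lists keyed by
    node id, with key 0 for the start node's children), ``reward_support``
    keyed by depth, and ``click_cost``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    layout = {int(k): tuple(v) for k, v in raw["layout"].items()}
    roots = layout.pop(0, None)
    if roots is None:
        raise TraceFormatError("layout must declare the start node's children"
                               " under key 0")
    support = {int(k): tuple(v) for k, v in raw["reward_support"].items()}
    return EnvConfig(
        children=layout,
        roots=tuple(roots),
        reward_support=support,
        click_cost=float(raw.get("click_cost", 1.0)),
    )
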