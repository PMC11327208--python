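"""Aggregating repeated runs with the majority heuristic.

Runs the pipeline several times on the same synthetic data, matches the
discovered strategies across runs by canonical formula equality, and keeps
only strategies found in a majority of runs — unstable descriptions are
noise and drop out.
"""

import numpy as np

from planlens import default_config
from planlens.aggregate import majority_select, match_strategies
from planlens.model_selection import NoQualifiedModelError
from planlens.pipeline import RunConfig, run_pipeline
from planlens.synthetic_data import default_specs, generate_dataset

N_RUNS, THRESHOLD = 5, 4  # scaled down from the 10-run / threshold-7 default

config = default_config()
rng = np.random.default_rng(42)
dataset = generate_dataset(default_specs(lapse=0.1), config, rng,
                           n_participants=40, n_trials=8, n_train=6)

outputs = []
for run in range(1, N_RUNS + 1):
    rc = RunConfig(run=run, begin=3, max_num_strategies=4, seed=42,
                   num_demos=32, em_restarts=2)
    try:
        outputs.append(run_pipeline(rc, trajectories=dataset.trajectories,
                                    write_files=False).output)
    except NoQualifiedModelError:
        print(f"run {run}: no model had all clusters described")

classes = match_strategies(outputs)
print(f"{len(outputs)} runs produced {len(classes)} distinct strategies:")
for c in classes:
    print(f"  in {c.multiplicity}/{len(outputs)} runs: "
          f"{c.key.splitlines()[0]} ...")

kept = majority_select(classes, n_runs=len(outputs), threshold=THRESHOLD)
print(f"\nmajority output at threshold {THRESHOLD}:")
for c in kept:
    print(f"\n{c.members[0].description or c.key}")
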