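"""From demonstrations to a procedural rule in natural language.

Samples demonstrations from a leaf-seeking policy, induces a DNF
description, orders it temporally with UNTIL conditions, and renders it as
numbered instructions.
"""

import numpy as np

from planlens import default_config
from planlens.clustering import (
    FEATURE_NAMES, N_FEATURES, SoftmaxPolicy, discretize, sample_demos)
from planlens.dnf2ltl import condition_pool, dnf_to_procedural
from planlens.dnf_learning import InterpretParams, interpret
from planlens.dsl import default_vocabulary
from planlens.translate import default_dictionary, render

config = default_config()
rng = np.random.default_rng(3)

# a leaf-seeking softmax policy: click leaves, stop once the 48 is revealed
w = np.zeros(N_FEATURES)
w[FEATURE_NAMES.index("is_leaf")] = 8.0
w[FEATURE_NAMES.index("is_term")] = -2.0
w[FEATURE_NAMES.index("term_max_reward_seen")] = 20.0
w[FEATURE_NAMES.index("term_all_leaves_observed")] = 30.0
demos = sample_demos(discretize(SoftmaxPolicy(w, config)), config, 32, rng)

vocabulary = default_vocabulary(config)
params = InterpretParams(depth=6, max_divergence=0.2, num_rollouts=48,
                         expert_reward=39.97)
result = interpret(demos, vocabulary, params, config, rng)
print(f"DNF description: {result.formula}")
print(f"  divergence {result.divergence:.3f} "
      f"(J_formula {result.j_formula:.2f} vs "
      f"J_interpreted {result.j_interpreted:.2f}), "
      f"{100 * result.used_fraction:.0f}% of demonstrations used")

procedural = dnf_to_procedural(
    result.formula, [list(r) for r in demos.rollouts],
    condition_pool(vocabulary), vocabulary, config)
print(f"\nprocedural formula:\n{procedural}")
print(f"\nnatural language:\n{render(procedural, default_dictionary(), config)}")
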