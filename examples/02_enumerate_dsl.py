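"""Enumerate the predicate DSL and evaluate a few predicates.

The grammar closes a small hand-made inventory under negation, among/all,
and bounded composition; the closure is the vocabulary from which strategy
descriptions are built.
"""

from planlens import default_config
from planlens.dsl import PredicateGrammar, enumerate_predicates
from planlens.env import BeliefState

config = default_config()
predicates = enumerate_predicates(PredicateGrammar.default(config))
print(f"full DSL closure: {len(predicates)} predicates")
print("a sample of the vocabulary:")
for p in predicates[:4] + predicates[50:52] + predicates[5000:5002]:
    print(f"  {p.name}")

belief = BeliefState().observe(1, 4).observe(7, 48)
by_name = {p.name: p for p in predicates}
for name in ("is_observed", "is_leaf", "is_max_observed",
             "all_roots_observed"):
    value = by_name[name].fn(belief, 8, config)
    print(f"{name}(belief after clicking 1 and 7, action=8) = {value}")
print("after revealing a 4 on node 1 and the 48 on leaf 7, clicking leaf 8 "
      "is an unobserved-leaf click in a state where the maximum reward has "
      "already surfaced.")
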