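# planlens

Automatic discovery and description of human planning strategies from
Mouselab-MDP process-tracing data.

Researchers who study how people plan externalize the planning process:
participants face a web of occluded nodes, pay a small fee to click a node
and reveal the reward beneath it, and finally commit to the path they
believe is best.  The resulting click sequences record which information
each person gathered, in which order, and when they decided they knew
enough.  Extracting the *strategies* behind those sequences — "inspect the
final outcomes until a 48 turns up, then stop" — has traditionally been
slow manual work.  `planlens` automates it end to end and is aimed at
cognitive scientists analyzing process-tracing experiments (and at anyone
who needs interpretable imitation of short sequential decision episodes).

## The method

A trial is a trajectory τ = ((s₁,a₁),…,(s_T,a_T)) of (belief state,
planning operation) pairs, ending with the stop operation `TERM`.  The
pipeline:

1. **Cluster.**  Fit a mixture of K softmax policies
   π_i(a|s) ∝ exp(f(s,a)ᵀw_i) over 19 state–action features by EM; each
   cluster is a candidate strategy.  Discretize each to the uniform
   distribution over its argmax operations and sample demonstration
   rollouts.
2. **Describe.**  Over a predicate DSL (boolean feature detectors
   f : S×A → {0,1}; the full grammar closure for the default environment
   has 27,838 predicates), find a DNF formula h = ⋁_i ⋀_j f_{i,j} that
   accepts the demonstrated operations and rejects the untaken
   alternatives, scored by a size prior × noisy classification
   likelihood.  Accept a candidate only if its induced policy's value
   stays within the divergence budget
   |J(π_f) − J(π̄_i)| / J(π_opt) ≤ α; otherwise drop the least promising
   demonstration sub-cluster and retry.
3. **Temporalize.**  Rewrite the DNF as a procedural formula — steps
   separated by NEXT, each followed UNTIL a state condition occurs (UNLESS
   another occurs), with GOTO loops — by reading phase structure off the
   demonstrations, then greedily prune literals to raise the likelihood of
   the cluster's human operations.
4. **Translate.**  Render each procedural formula as numbered
   natural-language instructions through a predicate-to-phrase dictionary.
5. **Select and aggregate.**  Score each K with an error-mixture
   likelihood P(τ|ε) = Σ_i (1/K) Π_j [ε_i π̄ᵢᵉʳʳ + (1−ε_i) π_i], pick the
   best K by BIC (models with undescribed clusters are disqualified), run
   the whole pipeline repeatedly, and keep strategies discovered in at
   least 7 of 10 runs.

A synthetic-participant generator (180 × 30 trials, named strategies,
lapse noise, latent labels) makes every stage testable without any
experimental data.  See `docs/methods.md` for the models, defaults and
caveats.

## A worked example

`examples/03_describe_demonstrations.py` samples 32 demonstrations from a
leaf-seeking softmax policy and runs the describe → temporalize →
translate chain:

```
DNF description: (is_leaf and not(is_max_observed)) OR (is_max_observed and is_term)
  divergence 0.018 (J_formula 37.56 vs J_interpreted 38.29), 100% of demonstrations used

procedural formula:
STEP 1: is_leaf UNTIL (all_leaves_observed or is_max_observed) NEXT
STEP 2: is_term UNTIL IT STOPS APPLYING

natural language:
1. Click on the nodes satisfying all of the following conditions: they are leaves. Repeat this step until all the leaves are observed or the previously observed node uncovers a 48.
2. Do not click. Repeat this step as long as possible.
```

The divergence line says the gap between the formula-induced policy's
value and the imitated policy's value is 1.8% of the optimal policy's
value — well inside the α = 0.2 acceptance budget — and the final text is
the strategy a human analyst would have written down.  The other examples cover the
environment simulator (`01`), the DSL (`02`), the full pipeline with BIC
model selection on a synthetic cohort (`04`), and cross-run aggregation
with the majority heuristic (`05`).

There is also a thin command line for running the pipeline on a
process-tracing CSV:

```bash
planlens --data traces.csv --run 1 --begin 3 --max_num_strategies 5 \
         --expert_reward 39.97 --num_demos 32
```

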