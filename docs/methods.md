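# Methods

`planlens` automates a two-stage analysis of Mouselab-MDP process-tracing
data: first a *generative* stage that compresses thousands of click
sequences into a small number of candidate planning strategies, then a
*descriptive* stage that turns each candidate into a human-readable,
step-by-step procedural rule.  This note records the models, the defaults,
and the design choices behind both stages, and what the synthetic-data
tests do and do not establish.

## The task and its state space

The benchmark environment is the increasing-variance Mouselab web: 3
branches, each a depth-1 → depth-2 → two depth-3 leaves chain (12 clickable
nodes, 6 start→leaf paths).  Hidden rewards are drawn i.i.d. uniform per
depth from {−4,−2,2,4}, {−8,−4,4,8} and {−48,−24,24,48}; each click costs
1.  A *belief state* is the ordered set of revealed nodes with their
values; a *planning operation* is a click on an unobserved node or the
decision to stop (`TERM`, action id 0; clickable ids are 1-based in
breadth-first order).  Terminating pays the best path's expected sum under
the current belief (observed values plus support means, which are 0 in the
default supports).  Episodes are at most 13 steps, so no discounting is
applied (γ is carried in the config but fixed to 1).  Re-clicking an
observed node is illegal; the CSV reader drops duplicate clicks with a
logged warning.

The layout is fully config-driven (YAML: child lists, per-depth supports,
click cost), so other webs can be declared without code changes.

## Clustering: a mixture of softmax policies

Each candidate strategy is a softmax policy over the legal operations,
`π_i(a|s) ∝ exp(f(s,a)ᵀ w_i)`, with P = 19 features: graph-structural
indicators of the clicked node (depth, leaf/root, sibling-of-previous,
same-branch-as-previous, parent/child observed) and belief-level stopping
context (fraction observed, scaled extreme observed values, whether the
maximum reward has surfaced, roots/leaves complete, the current
termination payoff, best-path observation fraction) plus a constant bias.
The belief-level features are attached to the `TERM` operation only: a
feature that is constant across the operations available in a belief
cancels out of the softmax, so stop rules such as "terminate once a 48 is
revealed" are linearly representable only if the stopping context lives on
the stopping action.

The mixture is fitted by soft-assignment EM.  The E-step computes
responsibilities at the level of *assignment units* — by default each
trajectory, optionally each participant (all of a participant's trials
share one assignment).  Participant-level units are the well-specified
model for data in which a strategy is a stable property of a person, and
they are what the recovery tests use: single trials are often too short to
identify a strategy (a one-click trial is consistent with several), while
30 trials per participant are decisive.  The M-step is a weighted
multinomial-logit fit per cluster (L-BFGS with analytic gradient, L2 ridge
10⁻⁴, 12 inner iterations per EM step with warm starts, one accurate
polish fit after convergence).  Mixing weights are fitted along with the
policy weights; with fixed uniform weights the likelihood rewards
splitting an over-represented strategy rather than isolating rare ones,
which defeats recovery whenever the true strategy frequencies are
unequal.  Stopping: absolute objective gain < 10⁻³ or relative gain
< 10⁻⁶ or 40 iterations; the best of the random restarts (random hard
partitions) is kept; near-empty clusters are re-seeded from the
worst-explained unit.  The tracked objective is the ridge-penalized
mixture log-likelihood and is non-decreasing up to optimizer tolerance.

Each fitted policy is discretized to an argmax policy (uniform over its
maximizing operations, ties at 10⁻⁹) and rolled out to produce
demonstrations for the description stage (32 rollouts by default in the
desk-scale configuration, 128 in the full configuration).

## The predicate DSL

Descriptions are built from boolean feature detectors on (belief,
operation) pairs.  The base inventory contains the action-level predicates
(`is_observed`, `is_leaf`, `is_root`, `depth_is_k`, `is_term`,
previous-click relations, observed-neighbour tests, `is_on_best_path`) and
the state-level predicates (`all_roots_observed`, `all_leaves_observed`,
`is_max_observed`, `is_positive_observed`, previous-click value tests,
…).  `is_observed` means "this node's reward has already been revealed",
so a legal click always satisfies `not(is_observed)`.

The full grammar closes this inventory under negation, the second-order
combinators `among(condition, pool)` (some node in a pool satisfies a
condition; conditions may be conjunctions of two node-level tests) and
`all(φ, ψ)` (every node satisfying φ satisfies ψ; vacuously true when
nothing satisfies φ), pairwise conjunctions of base predicates, and
pairwise disjunctions of state-level predicates.  For the default
environment the closure has 27,838 distinct, deterministically ordered
predicates.  The DNF search itself runs on the curated base vocabulary
(~23 predicates): evaluating the full closure on every demonstration is
possible but contributes nothing for the benchmark strategies, whose
concepts the base inventory already spans.  The vocabulary is an explicit
argument everywhere, so a larger closure subset can be substituted.

## Describing a cluster as a DNF formula

Demonstrated (belief, operation) pairs are positive examples; the untaken
legal alternatives in the same beliefs are negatives.  Candidate
descriptions are DNF formulas (depth = total literal count, default limit
6) scored by log P(formula) + log P(labels | formula) with a geometric
prior P ∝ 0.5^{#literals} and a noisy classification likelihood (each
example correct with probability 0.9).  Examples are class-balanced: each
demonstrated belief contributes one positive but ~12 negatives, and
without re-weighting the score would favour formulas that reject
operations inside the demonstrated policy's own support.  The always-true
formula (random clicking) is always among the candidates.  When the
bounded formula space is small the search scores it exhaustively;
otherwise it grows one conjunction greedily literal-by-literal, adds
further conjunctions for residual positives, and prunes locally.

A candidate is accepted when the uniform policy it induces (over the
operations it permits; terminating when it permits none) stays within the
divergence budget of the policy that produced the demonstrations:
`div = |J(π_f) − J(π̄_i)| / J(π_opt) ≤ α` with α = 0.2 and Monte-Carlo J
estimates (32 rollouts at desk scale).  The absolute difference is used: a
formula that out-earns the policy it imitates is also a mis-imitation.
`J(π_opt)` is a configuration input (39.97 for the benchmark environment);
computing the optimal metalevel policy is out of scope.  On failure, the
demonstrations are partitioned into valuation clusters (agglomerative,
Hamming distance, average linkage, 3 clusters by default), the cluster
with the smallest weighted posterior (size × best short-formula score) is
dropped, and the search retries; exhausting all clusters is a typed
failure, and the fraction of demonstrations used by the accepted formula
is always reported.

## From DNF to procedure

A DNF says which operations a strategy permits, not in which order its
disjuncts apply.  The conversion reads the order off the demonstration
rollouts: each operation is assigned to the first conjunction it satisfies
(a trailing `TERM` covered by no conjunction ends the trial), phases are
run-length encoded, and the modal phase sequence becomes the step
template; a periodic template compiles to a GOTO loop with an exit
condition.  Each step's UNTIL condition is the condition-pool element —
state-level predicates and their pairwise disjunctions — that is false
throughout the phase and true exactly at its end in the largest fraction
of rollouts (at least half, else the special "until it stops applying"
operator; ties prefer single predicates, then lexicographic order).
UNLESS conditions are searched after UNTIL, over the residual mismatches.

Step conjunctions are then canonically simplified using the temporal
structure: a literal asserting the previous step's UNTIL condition is
implied by step order; a literal negating this step's own UNTIL condition
is absorbed by the operator; a step that permits every legal operation at
every phase belief denotes complete uncertainty and becomes `True`; a step
that only ever permits termination becomes the bare termination literal.
These rules also make canonical strings stable across runs, which the
cross-run matching relies on.  Finally, literals are greedily pruned: one
deletion per iteration, the one that most increases the log-likelihood of
the cluster's *human* operations under the induced policy (disallowed
operations carry a 10⁻⁶ floor so the comparison is defined); ties keep the
literal, and the likelihood never decreases.

## Natural-language rendering

Rendering is a pure function of (formula, dictionary, environment).  Each
predicate has verbatim surface forms — a noun ("leaves"), an adjective
("unobserved"), and/or a free-standing clause — and operator templates
produce the numbered steps ("Click on the nodes satisfying all of the
following conditions: …", "Repeat this step until …", "Repeat this step as
long as possible.").  Environment constants are substituted at render time
("uncovers a 48").  The all-true step renders as "Terminate or click on
some random nodes and then terminate."; a termination-only formula renders
as "Do not click."  Negations without a hand-written entry fall back to
"it is not the case that …"; wording for predicates that never appear in
the benchmark outputs was chosen in the same register.

## Model selection over the number of strategies

For each K the described model is scored against the human trajectories
with an error-mixture likelihood: cluster i is a mixture of the uniform
policy over the operations its description currently allows (tracked
through the procedural phases) and an error model, the uniform policy over
the disallowed operations, with weight ε_i ∈ [0,1] under a Beta(α, β)
prior (default α = β = 1, i.e. MAP = MLE).  A trajectory's likelihood is
the uniform 1/K mixture over clusters of its per-step products.  ε is
fitted per cluster by EM with a grid M-step (the per-cluster objective is
one-dimensional); the penalized objective is non-decreasing.  Criteria:
BIC (default) with p = K free ε parameters and n = the total number of
planning operations (operations are the likelihood's atomic terms), AIC,
or a marginal likelihood that integrates each cluster's ε over its Beta
prior on a grid.  All criteria are reported higher-is-better.  Models with
any undescribed cluster are disqualified — whatever their likelihood, they
do not serve the purpose of understanding planning — and ties go to the
smaller K.

## Aggregation across runs

One run is stochastic, so the method repeats it (10 runs by default),
matches strategies across runs by canonical formula-string equality
(near-matches at Jaccard ≥ 0.8 over predicate sets are logged for review),
and keeps a strategy only if it appears in at least 7 of the runs.  The
threshold is calibrated by cross-validation over all 10-run subsets of a
larger run pool (C(21,10) = 352,716 for a 21-run pool), split 70/30,
maximizing mean detection accuracy on the training subsets; ties prefer
the larger (more conservative) threshold.  Reliability is summarized by
stability (the fraction of aggregated outputs equal to the modal output)
and variability (the mean symmetric-difference size over pairs of
differing outputs).

Per-strategy fit statistics: FR, the fraction of trajectories whose
maximum responsibility falls in the cluster; FCF, the mean of the two
directional agreement rates between description-policy demonstrations and
the cluster's argmax softmax policy (10,000 demonstration operations at
full scale); FON, the fraction of the cluster's human operations the
description allows; FPO, the ratio of the mean per-operation probability
of the human operations under the ε-mixture to the same quantity for
operations drawn from the description's policy *at the same beliefs*.  The
paired evaluation makes FPO exactly 1 for a cluster described by the
always-true formula, and keeps the statistic in [0, 1]-scale probability
space.

## The synthetic-data generator

The generator emulates the benchmark study's structure: 180 participants ×
30 trials (20 "train", 10 "test"), each participant committed to one named
strategy, i.i.d. per-step lapse noise (default 0.1: a step is replaced by
a uniformly random legal operation), fresh rewards per trial, and latent
labels stored in a sidecar table.  The built-in strategies are the four
benchmark families — explore unobserved leaves until the maximum reward
appears (or leaves are exhausted), the same with a preference for the
sibling of the previous click, no planning, and uniformly random planning
— with mixing proportions normalized from their reported frequencies
(16.7 : 31 : 22.6 : 4.3 → 0.224 : 0.416 : 0.303 : 0.058).

What the generator does not emulate: learning or strategy switching across
trials, feedback conditions, response times, and individual differences
beyond the strategy label.  Passing the recovery tests therefore shows
that the pipeline identifies stable, policy-consistent strategies under
realistic noise — not that it handles drifting or hybrid human behavior.

## Recovery tests: conditions and known limits

- EM assignment: at the full 180 × 30 condition with lapse 0.1 and the
  four planted strategies, participant-level hard assignments at the true
  K reach ARI ≥ 0.9 (typically 1.0).  Trial-level ARI is intrinsically
  lower: a one-click trial does not identify a strategy.
- Model order: with three well-separated strategies in equal proportion
  across 150 participants (4 trials each), the BIC scan over K = 1..5
  selects K = 3 in ≥ 8/10 seeded replications.  Equal proportions are the
  well-specified condition for the fixed-1/K selection mixture; sampling
  imbalance in small pools biases the criterion toward duplicated
  clusters.
- Aggregation: 10 runs on one 60 × 10 dataset with a BIC scan over
  K = 3..5 and majority threshold 7 recover ≥ 3 of the 4 planted
  strategies, identified behaviorally (mean Jaccard ≥ 0.75 between the
  description's allowed sets and the planted policy's support along
  planted rollouts).  The sibling-preference strategy is the one that
  collapses: expressing "an unobserved sibling of the previous click
  exists" needs a second-order predicate outside the curated search
  vocabulary, so its clusters converge to the plain leaf-exploration
  description.  This is the expected failure mode of a deliberately
  limited DSL, and extending the vocabulary is the documented remedy.

Problem sizes in the test suite (participants, trials, demonstration and
rollout counts) are the package's desk-scale configuration; the full-scale
defaults (128 demonstrations, 10,000 fit-statistic rollouts, 1–20
clusters) remain available through `RunConfig`.

## Numerical choices and degenerate inputs

Softmax probabilities are max-subtracted; mixture likelihoods are
evaluated in log space end to end (a 30-step trajectory cannot
underflow).  Argmax ties use a 10⁻⁹ absolute tolerance and split mass
evenly.  Formula policies with an empty satisfying set terminate.  An
empty conjunction is the always-true formula; a DNF with no conjunctions
is always false and is never produced by the search.  Degenerate
single-operation datasets fit with a warning; K greater than the number of
assignment units is an error.  All randomness flows through seeded
`numpy` generators; derived sub-seeds are drawn below 2³¹ and logged.
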