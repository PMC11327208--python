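"""Rule induction: example construction, induced policies, divergence,
the DNF search, and the full interpretation loop."""

import itertools

import numpy as np
import pytest

from planlens.clustering import (
    FEATURE_NAMES,
    N_FEATURES,
    SoftmaxPolicy,
    discretize,
    sample_demos,
)
from planlens.dnf_learning import (
    DNFFormula,
    ExampleSets,
    InterpretParams,
    Literal,
    build_examples,
    divergence,
    formula_policy,
    interpret,
    lpp_search,
    registry_of,
)
from planlens.dsl import base_predicates, default_vocabulary, valuation_matrix
from planlens.env import TERM, BeliefState, legal_operations, sample_rewards


def preds_by_name(config):
    return {p.name: p for p in base_predicates(config)}


class TestDNFFormula:
    def test_depth_is_total_literal_count(self):
        f = DNFFormula.from_literals(
            [Literal("a"), Literal("b", False)], [Literal("c")])
        assert f.depth == 3

    def test_contradictory_conjunction_rejected(self):
        with pytest.raises(ValueError):
            DNFFormula.from_literals([Literal("a"), Literal("a", False)])

    def test_canonical_equality_ignores_ordering(self):
        f = DNFFormula.from_literals([Literal("b"), Literal("a")], [Literal("c")])
        g = DNFFormula.from_literals([Literal("c")], [Literal("a"), Literal("b")])
        assert f == g and hash(f) == hash(g)


class TestBuildExamples:
    def test_single_demo_yields_twelve_negatives(self, config):
        ex = build_examples([(BeliefState(), 3)], config)
        assert len(ex.positives) == 1
        assert len(ex.negatives) == 12  # 11 other clicks + TERM

    def test_full_coverage_belief_contributes_no_negatives(self, config):
        belief = BeliefState()
        demos = [(belief, op) for op in legal_operations(belief, config)]
        ex = build_examples(demos, config)
        assert len(ex.negatives) == 0

    def test_positives_and_negatives_are_disjoint(self, config, rng):
        gt = sample_rewards(config, rng)
        belief = BeliefState().observe(1, gt[1])
        demos = [(BeliefState(), 1), (belief, 4), (belief, TERM)]
        ex = build_examples(demos, config)
        pos = {(b.clicks, o) for b, o in ex.positives}
        neg = {(b.clicks, o) for b, o in ex.negatives}
        assert not pos & neg

    def test_overlap_rejected_by_type(self, config):
        pair = (BeliefState(), 3)
        with pytest.raises(ValueError):
            ExampleSets(positives=[pair], negatives=[pair])


class TestFormulaPolicy:
    def test_not_observed_allows_all_clicks_and_term(self, config):
        preds = list(preds_by_name(config).values())
        f = DNFFormula.from_literals([Literal("is_observed", False)])
        pol = formula_policy(f, preds, config)
        probs = pol.probabilities(BeliefState())
        assert len(probs) == 13  # is_observed is false on TERM as well

    def test_unsatisfiable_formula_falls_back_to_term(self, config):
        preds = list(preds_by_name(config).values())
        f = DNFFormula.from_literals([Literal("is_leaf"), Literal("is_observed", False)])
        belief = BeliefState()
        for leaf in config.leaves:
            belief = belief.observe(leaf, 24)
        pol = formula_policy(f, preds, config)
        assert pol.probabilities(belief) == {TERM: 1.0}

    def test_true_formula_is_uniform_over_legal_ops(self, config):
        preds = list(preds_by_name(config).values())
        pol = formula_policy(DNFFormula.true(), preds, config)
        probs = pol.probabilities(BeliefState())
        assert len(probs) == 13
        assert all(p == pytest.approx(1 / 13) for p in probs.values())


class TestDivergence:
    def test_zero_when_equal(self):
        assert divergence(10.0, 10.0, 40.0) == 0.0

    def test_printed_arithmetic(self):
        assert divergence(30.0, 20.0, 40.0) == pytest.approx(0.25)

    def test_overshooting_formula_fails_the_budget(self):
        # interpreted reward R, formula reward 50R, optimal 100R: the old
        # reward-ratio criterion would accept, the divergence does not
        R = 1.0
        assert divergence(50 * R, R, 100 * R) == pytest.approx(0.49)
        assert divergence(50 * R, R, 100 * R) > 0.2

    def test_zero_expert_reward_is_an_error(self):
        with pytest.raises(ValueError):
            divergence(1.0, 1.0, 0.0)


def brute_force_best_score(examples, predicates, d, config):
    """Independent exhaustive enumeration of every DNF with total literal
    count <= d, scored with the class-balanced noisy-classification
    posterior; returns the best log score."""
    import math

    V_pos = valuation_matrix(examples.positives, predicates, config)
    V_neg = valuation_matrix(examples.negatives, predicates, config)
    n_pos, n_neg = len(V_pos), len(V_neg)
    w_pos = n_neg / n_pos if n_neg else 1.0
    w_total = w_pos * n_pos + n_neg

    def conj_masks(conj):
        p = np.ones(n_pos, dtype=bool)
        n = np.ones(n_neg, dtype=bool)
        for j, sign in conj:
            p &= V_pos[:, j] == sign
            n &= V_neg[:, j] == sign
        return p, n

    literals = list(range(len(predicates)))
    all_conjs = []
    for size in range(1, d + 1):
        for idxs in itertools.combinations(literals, size):
            for signs in itertools.product((True, False), repeat=size):
                all_conjs.append(tuple(zip(idxs, signs)))

    best = -math.inf
    # True formula (zero literals) accepts everything
    best = max(best, w_pos * n_pos * math.log(0.9) + n_neg * math.log(0.1))
    for k in range(1, d + 1):
        for sel in itertools.combinations(all_conjs, k):
            lits = sum(len(c) for c in sel)
            if lits > d:
                continue
            p = np.zeros(n_pos, dtype=bool)
            n = np.zeros(n_neg, dtype=bool)
            for c in sel:
                cp, cn = conj_masks(c)
                p |= cp
                n |= cn
            if not p.any():
                continue
            w_correct = w_pos * p.sum() + (~n).sum()
            score = (lits * math.log(0.5) + w_correct * math.log(0.9)
                     + (w_total - w_correct) * math.log(0.1))
            best = max(best, score)
    return best


def random_examples(config, rng, n_examples=8):
    pairs = []
    while len(pairs) < n_examples:
        gt = sample_rewards(config, rng)
        belief = BeliefState()
        for n in rng.permutation(config.nodes)[: rng.integers(0, 5)]:
            belief = belief.observe(int(n), gt[int(n)])
        ops = legal_operations(belief, config)
        pairs.append((belief, int(ops[rng.integers(len(ops))])))
    return build_examples(pairs, config)


class TestLPPSearch:
    def test_perfect_separator_is_top_candidate(self, config):
        preds = [preds_by_name(config)[n]
                 for n in ("is_leaf", "is_root", "is_term")]
        positives = [(BeliefState(), leaf) for leaf in config.leaves]
        negatives = [(BeliefState(), r) for r in config.roots]
        ex = ExampleSets(positives=positives, negatives=negatives)
        top = lpp_search(ex, preds, d=3, config=config)[0]
        assert top.formula == DNFFormula.from_literals([Literal("is_leaf")])

    def test_top_score_matches_bruteforce_small_instance(self, config):
        rng = np.random.default_rng(0)
        names = ("is_leaf", "is_root", "is_observed", "is_term",
                 "all_roots_observed", "is_max_observed")
        preds = [preds_by_name(config)[n] for n in names]
        ex = random_examples(config, rng, n_examples=6)
        ranked = lpp_search(ex, preds, d=3, config=config, top_k=3)
        oracle = brute_force_best_score(ex, preds, 3, config)
        assert ranked[0].score == pytest.approx(oracle, abs=1e-9)

    def test_no_positives_is_an_error(self, config):
        with pytest.raises(ValueError):
            lpp_search(ExampleSets([], []), default_vocabulary(config), 2, config)


def leaf_seeking_argmax(config):
    w = np.zeros(N_FEATURES)
    w[FEATURE_NAMES.index("is_root")] = 8.0
    w[FEATURE_NAMES.index("is_term")] = -2.0
    w[FEATURE_NAMES.index("term_all_roots_observed")] = 30.0
    return discretize(SoftmaxPolicy(w, config))


class TestInterpret:
    def test_round_trip_recovers_generating_formula(self, config):
        # demos generated by the policy of (not(is_observed) and is_root):
        # interpret should hand back a formula inducing the same policy
        rng = np.random.default_rng(4)
        demos = sample_demos(leaf_seeking_argmax(config), config, 24, rng)
        vocab = default_vocabulary(config)
        params = InterpretParams(depth=4, max_divergence=0.1,
                                 num_rollouts=48, expert_reward=39.97)
        result = interpret(demos, vocab, params, config, rng)
        assert result.success
        assert result.divergence <= params.max_divergence
        # the accepted formula allows exactly the unobserved roots at the
        # start and the roots-first support thereafter
        pol = formula_policy(result.formula, vocab, config)
        assert set(pol.allowed(BeliefState())) <= set(config.roots)

    def test_soundness_depth_and_divergence(self, config):
        rng = np.random.default_rng(8)
        demos = sample_demos(leaf_seeking_argmax(config), config, 16, rng)
        vocab = default_vocabulary(config)
        params = InterpretParams(depth=3, max_divergence=0.15,
                                 num_rollouts=32, expert_reward=39.97)
        result = interpret(demos, vocab, params, config, rng)
        if result.success:
            assert result.formula.depth <= params.depth
            assert result.divergence <= params.max_divergence
            assert 0.0 <= result.used_fraction <= 1.0

    def test_failure_is_a_typed_result(self, config):
        rng = np.random.default_rng(2)
        # a single demonstrated pair that no vocabulary predicate separates
        # within an impossible divergence budget of 0
        w = np.zeros(N_FEATURES)
        w[FEATURE_NAMES.index("click_depth_2")] = 10.0
        w[FEATURE_NAMES.index("term_fraction_observed")] = 200.0
        demos = sample_demos(discretize(SoftmaxPolicy(w, config)), config,
                             8, rng)
        params = InterpretParams(depth=1, max_divergence=0.0,
                                 num_rollouts=8, expert_reward=39.97)
        result = interpret(demos, default_vocabulary(config), params, config,
                           rng)
        assert result.formula is None or result.divergence == 0.0
        assert isinstance(result.used_fraction, float)
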