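"""Softmax features, mixture EM, discretization, demonstration sampling."""

import numpy as np
import pytest

from planlens.clustering import (
    FEATURE_NAMES,
    N_FEATURES,
    ArgmaxPolicy,
    FeaturizedData,
    SoftmaxPolicy,
    discretize,
    em_fit,
    featurize,
    sample_demos,
    softmax_prob,
)
from planlens.env import (
    TERM,
    BeliefState,
    Trajectory,
    best_path,
    legal_operations,
    sample_rewards,
    term_reward,
)
from planlens.synthetic_data import (
    LeafUntilMaxPolicy,
    NoPlanningPolicy,
    StrategySpec,
    generate_dataset,
)


class TestFeaturize:
    def test_term_on_empty_belief(self, config):
        x = featurize(BeliefState(), TERM, config)
        names = dict(zip(FEATURE_NAMES, x))
        assert names["is_term"] == 1.0
        assert names["click_depth_1"] == 0.0
        assert names["click_depth_3"] == 0.0
        assert names["bias"] == 1.0

    def test_leaf_click_sets_leaf_indicator(self, config):
        x = featurize(BeliefState(), 7, config)
        names = dict(zip(FEATURE_NAMES, x))
        assert names["is_leaf"] == 1.0 and names["click_depth_3"] == 1.0

    def test_componentwise_oracle_on_random_pairs(self, config, rng):
        # recompute each feature independently of the packed implementation
        for _ in range(50):
            gt = sample_rewards(config, rng)
            belief = BeliefState()
            for n in rng.permutation(config.nodes)[: rng.integers(0, 8)]:
                belief = belief.observe(int(n), gt[int(n)])
            ops = legal_operations(belief, config)
            op = int(ops[rng.integers(len(ops))])
            x = dict(zip(FEATURE_NAMES, featurize(belief, op, config)))
            assert x["is_term"] == float(op == TERM)
            if op != TERM:
                assert x["is_leaf"] == float(op in config.leaves)
                assert x["is_root"] == float(op in config.roots)
                prev = belief.last_click
                if prev is not None:
                    assert x["sibling_of_previous"] == float(
                        op in config.siblings[prev])
                assert x["parent_observed"] == float(
                    config.parent.get(op) in belief.observed)
                assert x["term_max_reward_seen"] == 0.0
            else:
                assert x["term_fraction_observed"] == pytest.approx(
                    len(belief.observed) / config.n_nodes)
                assert x["term_reward_scaled"] == pytest.approx(
                    term_reward(belief, config) / config.max_reward)
                bp = best_path(belief, config)
                assert x["term_best_path_observed_fraction"] == pytest.approx(
                    sum(1 for n in bp if n in belief.observed) / len(bp))


class TestSoftmaxPolicy:
    def test_zero_weights_are_uniform_over_legal_ops(self, config):
        pol = SoftmaxPolicy(np.zeros(N_FEATURES), config)
        probs = pol.probabilities(BeliefState())
        assert len(probs) == 13
        assert all(p == pytest.approx(1 / 13) for p in probs.values())

    def test_probabilities_sum_to_one(self, config, rng):
        for _ in range(100):
            w = rng.normal(size=N_FEATURES)
            belief = BeliefState()
            for n in rng.permutation(config.nodes)[: rng.integers(0, 8)]:
                belief = belief.observe(int(n), 24)
            pol = SoftmaxPolicy(w, config)
            assert sum(pol.probabilities(belief).values()) == pytest.approx(1.0)

    def test_heavy_leaf_weight_concentrates_on_leaves(self, config):
        w = np.zeros(N_FEATURES)
        w[FEATURE_NAMES.index("is_leaf")] = 20.0
        pol = SoftmaxPolicy(w, config)
        probs = pol.probabilities(BeliefState())
        leaf_mass = sum(p for o, p in probs.items() if o in config.leaves)
        assert leaf_mass >= 0.99

    def test_softmax_prob_matches_direct_formula(self, config, rng):
        w = rng.normal(size=N_FEATURES)
        pol = SoftmaxPolicy(w, config)
        belief = BeliefState().observe(1, 4)
        ops = legal_operations(belief, config)
        logits = np.array([featurize(belief, o, config) @ w for o in ops])
        expected = np.exp(logits - logits.max())
        expected /= expected.sum()
        for o, e in zip(ops, expected):
            assert softmax_prob(pol, belief, o) == pytest.approx(e)


class TestDiscretize:
    def test_zero_weights_discretize_to_uniform(self, config):
        pol = discretize(SoftmaxPolicy(np.zeros(N_FEATURES), config))
        probs = pol.probabilities(BeliefState())
        assert len(probs) == 13
        assert all(p == pytest.approx(1 / 13) for p in probs.values())

    def test_unique_maximizer_is_deterministic(self, config):
        w = np.zeros(N_FEATURES)
        w[FEATURE_NAMES.index("is_term")] = 5.0
        pol = discretize(SoftmaxPolicy(w, config))
        assert pol.probabilities(BeliefState()) == {TERM: 1.0}

    def test_two_way_tie_splits_mass_evenly(self, config):
        w = np.zeros(N_FEATURES)
        w[FEATURE_NAMES.index("is_root")] = 3.0
        w[FEATURE_NAMES.index("click_depth_1")] = 3.0
        pol = discretize(SoftmaxPolicy(w, config))
        belief = BeliefState().observe(1, 4)  # two roots remain
        probs = pol.probabilities(belief)
        assert probs == {2: pytest.approx(0.5), 3: pytest.approx(0.5)}

    def test_idempotence(self, config):
        base = SoftmaxPolicy(np.arange(N_FEATURES, dtype=float) / 10, config)
        once = discretize(base)
        assert discretize(once) is once


def planted_trajectories(config, rng, n=100):
    specs = [
        StrategySpec("leaf", LeafUntilMaxPolicy, 0.5, 0.0),
        StrategySpec("none", lambda c: NoPlanningPolicy(), 0.5, 0.0),
    ]
    ds = generate_dataset(specs, config, rng, n_participants=n, n_trials=2,
                          n_train=2)
    return ds


def leaf_seeking_weights():
    w = np.zeros(N_FEATURES)
    w[FEATURE_NAMES.index("is_leaf")] = 8.0
    w[FEATURE_NAMES.index("is_term")] = -2.0
    w[FEATURE_NAMES.index("term_max_reward_seen")] = 20.0
    w[FEATURE_NAMES.index("term_all_leaves_observed")] = 30.0
    return w


def term_seeking_weights():
    w = np.zeros(N_FEATURES)
    w[FEATURE_NAMES.index("is_term")] = 10.0
    return w


class TestEMFit:
    def test_k1_equals_single_policy_fit(self, config, rng):
        ds = planted_trajectories(config, rng, n=30)
        model = em_fit(ds.trajectories, 1, config, rng, n_restarts=1)
        data = FeaturizedData.from_trajectories(ds.trajectories, config)
        direct = float(data.traj_loglik(model.policies[0].weights).sum())
        assert model.data_loglik == pytest.approx(direct, abs=1e-6)

    def test_two_planted_softmax_policies_recovered(self, config):
        # trajectories sampled from two known softmax policies (leaf-seeking
        # vs immediate-TERM); EM at K=2 should reassign them almost perfectly
        from planlens.env import Trajectory, rollout

        rng = np.random.default_rng(5)
        trajs, labels = [], []
        for name, w in (("leaf", leaf_seeking_weights()),
                        ("term", term_seeking_weights())):
            pol = SoftmaxPolicy(w, config)
            for i in range(100):
                steps, _ = rollout(pol, config, rng)
                trajs.append(Trajectory(steps=steps, participant_id=f"{name}{i}"))
                labels.append(name)
        model = em_fit(trajs, 2, config, rng, n_restarts=2)
        hard = model.hard_assignments()
        labels = np.array(labels)
        acc = 0
        for k in (0, 1):
            _, counts = np.unique(labels[hard == k], return_counts=True)
            acc += counts.max() if len(counts) else 0
        assert acc / len(labels) >= 0.95

    def test_loglik_trace_is_non_decreasing(self, config, rng):
        ds = planted_trajectories(config, rng, n=40)
        model = em_fit(ds.trajectories, 3, config, rng, n_restarts=1)
        trace = np.array(model.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-5)

    def test_order_invariance_k1(self, config, rng):
        ds = planted_trajectories(config, rng, n=30)
        a = em_fit(ds.trajectories, 1, config, np.random.default_rng(0),
                   n_restarts=1)
        b = em_fit(list(reversed(ds.trajectories)), 1, config,
                   np.random.default_rng(0), n_restarts=1)
        assert a.loglik == pytest.approx(b.loglik, rel=1e-6)

    def test_k_larger_than_data_raises(self, config, rng):
        ds = planted_trajectories(config, rng, n=2)
        with pytest.raises(ValueError):
            em_fit(ds.trajectories, 50, config, rng)

    def test_degenerate_single_operation_data_warns(self, config, rng):
        steps = ((BeliefState(), TERM),)
        trajs = [Trajectory(steps=steps, participant_id=f"p{i}")
                 for i in range(5)]
        with pytest.warns(UserWarning):
            em_fit(trajs, 1, config, rng, n_restarts=1, max_iter=3)


class TestSampleDemos:
    def test_immediate_term_policy_gives_only_term_pairs(self, config, rng):
        w = np.zeros(N_FEATURES)
        w[FEATURE_NAMES.index("is_term")] = 10.0
        pol = discretize(SoftmaxPolicy(w, config))
        demos = sample_demos(pol, config, 128, rng)
        assert len(demos.pairs) == 128
        assert all(op == TERM for _, op in demos.pairs)

    def test_leaf_policy_demo_pairs_are_unobserved_leaves(self, config, rng):
        from planlens.dsl import base_predicates
        preds = {p.name: p for p in base_predicates(config)}
        w = np.zeros(N_FEATURES)
        w[FEATURE_NAMES.index("is_leaf")] = 10.0
        w[FEATURE_NAMES.index("term_all_leaves_observed")] = 30.0
        w[FEATURE_NAMES.index("is_term")] = -5.0
        pol = discretize(SoftmaxPolicy(w, config))
        demos = sample_demos(pol, config, 10, rng)
        for belief, op in demos.pairs:
            if op != TERM:
                assert preds["is_leaf"].fn(belief, op, config)
                assert not preds["is_observed"].fn(belief, op, config)

    def test_fixed_seed_reproduces_demos(self, config):
        pol = discretize(SoftmaxPolicy(np.zeros(N_FEATURES), config))
        a = sample_demos(pol, config, 16, np.random.default_rng(9))
        b = sample_demos(pol, config, 16, np.random.default_rng(9))
        assert a.rollouts == b.rollouts
        assert a.seed == b.seed
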