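"""Cross-run aggregation: matching, majority heuristic, threshold
calibration, detection metrics, stability/variability, fit statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from planlens.aggregate import (
    ClusterData,
    DetectionCounts,
    DiscoveredStrategy,
    RunOutput,
    calibrate_threshold,
    count_run_subsets,
    detection_metrics,
    enumerate_run_subsets,
    fit_statistics,
    majority_select,
    match_strategies,
    stability_variability,
)
from planlens.clustering import (
    FEATURE_NAMES,
    N_FEATURES,
    SoftmaxPolicy,
    discretize,
)
from planlens.dnf2ltl import Condition, ProceduralFormula, Step, UNTIL_STOPS
from planlens.dnf_learning import Literal
from planlens.dsl import base_predicates
from planlens.env import TERM, BeliefState, Trajectory


def formula(*names):
    return ProceduralFormula(steps=(
        Step(frozenset(Literal(n) for n in names), UNTIL_STOPS),))


def run_output(run_id, formulas):
    return RunOutput(run_id=run_id, K=len(formulas), strategies=[
        DiscoveredStrategy(formula=f, description="", run_id=run_id,
                           cluster_id=i)
        for i, f in enumerate(formulas)
    ])


class TestMatchStrategies:
    def test_identical_formulas_form_one_class(self):
        runs = [run_output(i, [formula("is_leaf")]) for i in range(3)]
        classes = match_strategies(runs)
        assert len(classes) == 1 and classes[0].multiplicity == 3

    def test_one_literal_difference_separates_classes(self, caplog):
        runs = [run_output(1, [formula("is_leaf", "is_root")]),
                run_output(2, [formula("is_leaf")])]
        with caplog.at_level("INFO"):
            classes = match_strategies(runs)
        assert len(classes) == 2

    def test_ten_runs_with_four_stable_strategies(self):
        formulas = [formula("is_leaf"), formula("is_term"),
                    formula("is_root"), formula("is_observed")]
        runs = [run_output(r, formulas) for r in range(10)]
        classes = match_strategies(runs)
        assert len(classes) == 4
        assert all(c.multiplicity == 10 for c in classes)

    def test_single_run_is_an_error(self):
        with pytest.raises(ValueError):
            match_strategies([run_output(1, [formula("is_leaf")])])


class TestMajoritySelect:
    def make_classes(self, mults):
        runs = []
        for r in range(10):
            fs = [formula(f"f{i}") for i, m in enumerate(mults) if r < m]
            runs.append(run_output(r, fs))
        return match_strategies(runs)

    def test_seven_of_ten_is_included(self):
        classes = self.make_classes([7])
        assert len(majority_select(classes, 10, 7)) == 1

    def test_six_of_ten_is_excluded(self):
        classes = self.make_classes([6])
        assert len(majority_select(classes, 10, 7)) == 0

    def test_threshold_one_keeps_everything(self):
        classes = self.make_classes([1, 4, 9])
        assert len(majority_select(classes, 10, 1)) == 3

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            majority_select([], 10, 11)


class TestDetectionMetrics:
    def test_printed_counts(self):
        # |S|=21, |G|=10, |B|=5 with 4 true positives
        universe = frozenset(f"s{i}" for i in range(21))
        G = frozenset(f"s{i}" for i in range(10))
        B = frozenset(["s0", "s1", "s2", "s3", "s20"])
        m = detection_metrics(DetectionCounts(universe, G, B))
        assert round(m.accuracy, 2) == 0.67
        assert round(m.precision, 2) == 0.80
        assert round(m.recall, 2) == 0.40
        assert round(m.f1, 2) == 0.53

    def test_perfect_discovery(self):
        u = frozenset("abc")
        m = detection_metrics(DetectionCounts(u, u, u))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1, 1, 1, 1)

    def test_disjoint_nonempty_sets(self):
        u = frozenset("abcd")
        m = detection_metrics(DetectionCounts(u, frozenset("ab"),
                                              frozenset("cd")))
        assert m.precision == 0 and m.recall == 0 and m.f1 == 0

    def test_empty_discovered_flags_precision(self):
        u = frozenset("ab")
        m = detection_metrics(DetectionCounts(u, frozenset("a"), frozenset()))
        assert m.precision is None and "precision" in m.undefined

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_confusion_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 15))
        universe = frozenset(f"s{i}" for i in range(n))
        G = frozenset(s for s in universe if rng.random() < 0.5)
        B = frozenset(s for s in universe if rng.random() < 0.5)
        m = detection_metrics(DetectionCounts(universe, G, B))
        tp = len(B & G)
        fp = len(B - G)
        fn = len(G - B)
        tn = n - tp - fp - fn
        assert m.accuracy == pytest.approx((tp + tn) / n)
        if B:
            assert m.precision == pytest.approx(tp / len(B))
        if G:
            assert m.recall == pytest.approx(tp / len(G))
        if B and G and (m.precision + m.recall) > 0:
            assert m.f1 == pytest.approx(
                2 * m.precision * m.recall / (m.precision + m.recall))


class TestThresholdCalibration:
    def test_subset_count_for_pool_of_twelve(self):
        assert count_run_subsets(12, 10) == math.comb(12, 10)
        assert sum(1 for _ in enumerate_run_subsets(12, 10)) == 66

    def test_perfect_pool_prefers_largest_threshold(self, rng):
        gt = {formula("is_leaf").canonical(), formula("is_term").canonical()}
        runs = [run_output(r, [formula("is_leaf"), formula("is_term")])
                for r in range(11)]
        res = calibrate_threshold(runs, gt, rng)
        assert res.threshold == 10  # any threshold is optimal; tie -> largest
        assert res.train_accuracy == pytest.approx(1.0)

    def test_planted_noise_pushes_threshold_up(self, rng):
        gt = {formula("is_leaf").canonical()}
        runs = []
        for r in range(12):
            fs = [formula("is_leaf")]
            if r < 3:  # noise strategy present in only 3 runs
                fs.append(formula(f"noise"))
            runs.append(run_output(r, fs))
        res = calibrate_threshold(runs, gt, rng)
        assert res.threshold >= 4

    def test_empty_ground_truth_is_an_error(self, rng):
        runs = [run_output(r, [formula("is_leaf")]) for r in range(10)]
        with pytest.raises(ValueError):
            calibrate_threshold(runs, set(), rng)


class TestStabilityVariability:
    def test_identical_outputs(self):
        s, v = stability_variability([{"a", "b"}] * 5)
        assert s == 1.0 and v == 0.0

    def test_enumerated_example(self):
        s, v = stability_variability([{"a", "b"}, {"a", "b"}, {"a"}])
        assert s == pytest.approx(2 / 3)
        assert v == pytest.approx(1.0)  # the two differing pairs differ by 1

    def test_seeded_pool_matches_analytic_values(self):
        # constructed mixture: modal output with probability 0.7, otherwise
        # the modal output missing one strategy
        rng = np.random.default_rng(0)
        modal = frozenset({"a", "b", "c"})
        alt = frozenset({"a", "b"})
        pool = [modal if rng.random() < 0.7 else alt for _ in range(400)]
        s, v = stability_variability(pool)
        p = sum(1 for x in pool if x == modal) / len(pool)
        se = math.sqrt(0.7 * 0.3 / len(pool))
        assert abs(s - 0.7) < 3 * se
        assert v == pytest.approx(1.0)  # every differing pair differs by 1

    def test_needs_at_least_two(self):
        with pytest.raises(ValueError):
            stability_variability([{"a"}])


class TestFitStatistics:
    def term_cluster(self, config, n_members=5, n_total=10):
        trajs = [Trajectory(steps=((BeliefState(), TERM),),
                            participant_id=f"p{i}") for i in range(n_members)]
        w = np.zeros(N_FEATURES)
        w[FEATURE_NAMES.index("is_term")] = 10.0
        return ClusterData(
            member_trajectories=trajs,
            softmax_argmax=discretize(SoftmaxPolicy(w, config)),
            description=ProceduralFormula(steps=(
                Step(frozenset({Literal("is_term")}), UNTIL_STOPS),)),
            n_total_trajectories=n_total,
        )

    def test_random_description_fpo_is_exactly_one(self, config, rng):
        # the True formula's induced policy is uniform; evaluated at the same
        # beliefs, member and description-sampled operations are equally
        # likely, so FPO = 1 exactly
        trajs = [Trajectory(steps=((BeliefState(), 7),
                                   (BeliefState().observe(7, 24), TERM)),
                            participant_id="p0")]
        cd = ClusterData(
            member_trajectories=trajs,
            softmax_argmax=discretize(SoftmaxPolicy(np.zeros(N_FEATURES),
                                                    config)),
            description=ProceduralFormula(steps=(
                Step(frozenset(), UNTIL_STOPS),)),
            n_total_trajectories=4,
            epsilon=0.1,
        )
        stats = fit_statistics(cd, base_predicates(config), config, rng,
                               n_demos=200)
        assert stats.FPO == pytest.approx(1.0)

    def test_perfectly_described_cluster(self, config, rng):
        cd = self.term_cluster(config)
        stats = fit_statistics(cd, base_predicates(config), config, rng,
                               n_demos=200)
        assert stats.FON == pytest.approx(1.0)
        assert stats.FCF == pytest.approx(1.0)
        assert stats.FR == pytest.approx(0.5)

    def test_lapse_cluster_fon_near_lapse_rate(self, config):
        # members follow the TERM description except ~20% lapse clicks
        rng = np.random.default_rng(6)
        trajs = []
        for i in range(300):
            if rng.random() < 0.2:
                b1 = BeliefState().observe(3, 2)
                trajs.append(Trajectory(
                    steps=((BeliefState(), 3), (b1, TERM)),
                    participant_id=f"p{i}"))
            else:
                trajs.append(Trajectory(steps=((BeliefState(), TERM),),
                                        participant_id=f"p{i}"))
        cd = self.term_cluster(config)
        cd.member_trajectories = trajs
        cd.n_total_trajectories = 300
        stats = fit_statistics(cd, base_predicates(config), config, rng,
                               n_demos=100)
        # per-operation: lapse trials contribute one disallowed click and one
        # allowed TERM; expected FON = (0.8*1 + 0.2*2*0.5 ops) accounted at
        # operation level
        n_ops = sum(len(t) for t in trajs)
        n_disallowed = sum(1 for t in trajs if len(t) == 2)
        expected = 1 - n_disallowed / n_ops
        assert stats.FON == pytest.approx(expected)

    def test_empty_cluster_is_an_error(self, config, rng):
        cd = self.term_cluster(config)
        cd.member_trajectories = []
        with pytest.raises(ValueError):
            fit_statistics(cd, base_predicates(config), config, rng)


class TestFinalReport:
    def test_text_and_json_written(self, tmp_path):
        from planlens.aggregate import write_final_report
        import json

        runs = [run_output(r, [formula("is_leaf"), formula("is_term")])
                for r in range(3)]
        for out in runs:
            for s in out.strategies:
                s.statistics = {"FR": 0.5, "FON": 1.0}
                s.description = "Do not click."
        classes = match_strategies(runs)
        write_final_report(classes, 3, tmp_path / "report.txt",
                           tmp_path / "report.json")
        text = (tmp_path / "report.txt").read_text()
        assert "in 3/3 runs" in text and "FR=0.500" in text
        records = json.loads((tmp_path / "report.json").read_text())
        assert len(records) == 2
        assert records[0]["runs"] == 3
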