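import numpy as np
import pytest

from zebra3d import (FuzzyART, FuzzyARTParams, Segment, SimConfig, SplitSpec,
                     StimulusSchedule, cluster_profiles, compare_cluster_params,
                     evaluate_transfer, hierarchy, run_experiment,
                     segment_trajectory, simulate_trajectory, split_segments)
from zebra3d.assoc import binomial_association, run_cell
from zebra3d.core import PHASE_ES, PHASE_QT
from zebra3d.features import FeaturePipeline


def toy_segments(n, phase_cycle=("QT", "ES")):
    rng = np.random.default_rng(0)
    segs = []
    for i in range(n):
        xyz = rng.uniform(0, 20, (30, 3))
        segs.append(Segment(fish_id=0, phase=phase_cycle[i % len(phase_cycle)],
                            start_s=float(i), duration_s=0.5, xyz=xyz,
                            fps=60.0))
    return segs


class TestSplit:
    def test_80_20_counts(self):
        train, test = split_segments(toy_segments(100),
                                     SplitSpec(stratify_by="none"))
        assert len(train) == 80 and len(test) == 20

    def test_same_seed_same_split(self):
        segs = toy_segments(60)
        s1 = split_segments(segs, SplitSpec(seed=5))
        s2 = split_segments(segs, SplitSpec(seed=5))
        assert [id(s) for s in s1[0]] == [id(s) for s in s2[0]]

    def test_stratified_counts(self):
        segs = toy_segments(120)           # 60 QT + 60 ES interleaved
        train, test = split_segments(segs, SplitSpec(stratify_by="phase"))
        for group, n_expect in ((train, 48), (test, 12)):
            for ph in (PHASE_QT, PHASE_ES):
                assert sum(s.phase == ph for s in group) == n_expect

    def test_disjoint_and_exhaustive(self):
        segs = toy_segments(33)
        train, test = split_segments(segs, SplitSpec(seed=2))
        assert len(train) + len(test) == 33
        assert {id(s) for s in train}.isdisjoint({id(s) for s in test})


def fitted_state(segments):
    phases = np.array([s.phase for s in segments], dtype=object)
    return run_cell(segments, phases, 0.9, 0.5)


class TestEvaluateTransfer:
    def test_single_category_counts_all_test_rows(self):
        segs = toy_segments(24)
        X01, pipeline = FeaturePipeline.fit(segs, target_cum_var=0.72)
        model = FuzzyART(FuzzyARTParams(rho=0.0)).fit(X01)
        test = toy_segments(6, phase_cycle=("ES",))
        table = evaluate_transfer(model, [], test, pipeline)
        assert table["count_es_test"].sum() == 6
        assert table["count_qt_test"].sum() == 0

    def test_empty_test_set_gives_empty_counts(self):
        segs = toy_segments(24)
        model, pipeline, results = fitted_state(segs)
        table = evaluate_transfer(model, results, [], pipeline)
        assert (table["count_es_test"] == 0).all()

    def test_leakage_guard_rejects_mismatched_state(self):
        segs = toy_segments(24)
        model, _, results = fitted_state(segs)
        _, wrong_pipeline = FeaturePipeline.fit(toy_segments(30),
                                                target_cum_var=0.9)
        with pytest.raises(ValueError, match="training"):
            evaluate_transfer(model, results, toy_segments(4), wrong_pipeline)

    def test_test_rows_cannot_alter_training_state(self):
        segs = toy_segments(24)
        model, pipeline, results = fitted_state(segs)
        W = model.W_.copy()
        corrupted = toy_segments(8)
        for s in corrupted:
            s.xyz *= 100.0                # way outside training range
        evaluate_transfer(model, results, corrupted, pipeline)
        assert np.array_equal(W, model.W_)


class TestProfilesAndHierarchy:
    def test_identical_profiles_merge_at_zero(self):
        segs = toy_segments(8, phase_cycle=("QT",))
        assignments = np.zeros(8, int)
        p_train = cluster_profiles(segs, assignments, "train", 10.0)
        p_test = cluster_profiles(segs, assignments, "test", 10.0)
        Z, order = hierarchy(p_train + p_test)
        assert Z[0, 2] == pytest.approx(0.0)
        assert set(order) == {("train", 0), ("test", 0)}

    def test_single_profile_empty_linkage(self):
        segs = toy_segments(4, phase_cycle=("QT",))
        profs = cluster_profiles(segs, np.zeros(4, int), "train", 10.0)
        Z, order = hierarchy(profs)
        assert Z.shape == (0, 4)
        assert order == [("train", 0)]

    def test_matched_train_test_clusters_are_neighbors(self):
        """A slow and a fast cluster: the train/test profiles of the same
        cluster should merge before the two clusters do."""
        rng = np.random.default_rng(1)
        def walk(speed):
            steps = rng.normal(0, speed, (60, 3))
            return np.clip(np.cumsum(steps, axis=0) + 10.0, 0, 20)
        slow = [Segment(0, "QT", i, 1.0, walk(0.02), 60.0) for i in range(8)]
        fast = [Segment(0, "ES", i, 1.0, walk(0.5), 60.0) for i in range(8)]
        segs = slow + fast
        assignments = np.array([0] * 8 + [1] * 8)
        profs = (cluster_profiles(segs[:4] + segs[8:12],
                                  assignments[[*range(4), *range(8, 12)]],
                                  "train", 10.0)
                 + cluster_profiles(segs[4:8] + segs[12:],
                                    assignments[[*range(4, 8), *range(12, 16)]],
                                    "test", 10.0))
        Z, _ = hierarchy(profs)
        # first two merges are within-cluster, across sources
        first = {frozenset({0, 1}), frozenset({2, 3})}
        merges = {frozenset({int(Z[i, 0]), int(Z[i, 1])}) for i in (0, 1)}
        keys = sorted([(p.source, p.cluster) for p in sorted(
            profs, key=lambda p: (p.source, p.cluster))])
        # leaves: 0=(test,0) 1=(test,1) 2=(train,0) 3=(train,1)
        assert merges == {frozenset({0, 2}), frozenset({1, 3})}


class TestCompareClusterParams:
    def test_identical_groups_null(self):
        segs = toy_segments(6, phase_cycle=("QT",))
        table = compare_cluster_params(segs, [Segment(s.fish_id, s.phase,
                                                      s.start_s, s.duration_s,
                                                      s.xyz.copy(), s.fps)
                                              for s in segs], 10.0)
        assert np.allclose(table["t"], 0.0)
        assert np.allclose(table["p"], 1.0)

    def test_welch_matches_manual_formula(self):
        def seg_with_speed(v, i):
            n = 61
            t = np.arange(n) / 60.0
            xyz = np.column_stack([v * t, np.zeros(n), np.full(n, 5.0)])
            return Segment(0, "QT", float(i), 1.0, xyz, 60.0)
        a = [seg_with_speed(v, i) for i, v in enumerate((1.0, 2.0, 3.0))]
        b = [seg_with_speed(v, i) for i, v in enumerate((2.0, 3.0, 4.0))]
        table = compare_cluster_params(a, b, 10.0).set_index("parameter")
        # Welch t for {1,2,3} vs {2,3,4}: t = -1/sqrt(2/3)
        expected = -1.0 / np.sqrt(2.0 / 3.0)
        assert table.loc["average_speed", "t"] == pytest.approx(expected)

    def test_speed_shift_detected(self):
        rng = np.random.default_rng(2)
        def group(base):
            out = []
            for i in range(20):
                steps = rng.normal(0, base, (60, 3))
                xyz = np.clip(np.cumsum(steps, axis=0) + 10, 0, 20)
                out.append(Segment(0, "QT", float(i), 1.0, xyz, 60.0))
            return out
        table = compare_cluster_params(group(0.05), group(0.5), 10.0)
        row = table.set_index("parameter").loc["average_speed"]
        assert row["p"] < 1e-6

    def test_small_groups_rejected(self):
        segs = toy_segments(4)
        with pytest.raises(ValueError):
            compare_cluster_params(segs[:1], segs[1:], 10.0)


class TestRunExperiment:
    def test_motif_recovered_end_to_end(self):
        cfg = SimConfig(n_fish=4,
                        schedule=StimulusSchedule.alternating(30, 30, 5),
                        seed=17)
        trajs = [simulate_trajectory(cfg, f) for f in range(cfg.n_fish)]
        res = run_experiment(trajs, split=SplitSpec(seed=17))
        assert res.model.n_categories > 1
        assert len(res.es_specific) >= 1
        es_rows = res.transfer[res.transfer["train_direction"] == "ES"]
        assert (es_rows["count_es_test"].sum()
                > es_rows["count_qt_test"].sum())

    def test_summary_is_json_serializable(self):
        import json
        cfg = SimConfig(n_fish=2,
                        schedule=StimulusSchedule.alternating(30, 30, 2),
                        seed=8)
        trajs = [simulate_trajectory(cfg, f) for f in range(2)]
        res = run_experiment(trajs, split=SplitSpec(seed=8))
        json.dumps(res.summary())
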