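import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from embryotrack.forest import LineageForest
from embryotrack.metrics import (
    dispersion_index,
    division_precision_recall,
    edge_error_rate,
    error_free_stats,
    expression_velocity_correlation,
    global_point_matching,
    match_detections,
    mixing_index,
    velocity_field,
)


def linear_forest(n_frames, offset=(0.0, 0.0, 0.0), speed=1.0):
    f = LineageForest()
    prev = None
    for t in range(n_frames):
        n = f.add_node(t, np.add(offset, (0.0, 0.0, speed * t)))
        if prev is not None:
            f.add_edge(prev, n)
        prev = n
    return f


class TestMatching:
    def test_identical_forests_identity_mapping(self):
        f = linear_forest(4)
        corr = match_detections(f, f, radius_um=1.0)
        assert corr.gt_to_pred == {n: n for n in f.nodes()}

    def test_node_beyond_radius_unmatched(self):
        gt = linear_forest(2)
        pred = linear_forest(2, offset=(0.0, 10.0, 0.0))
        corr = match_detections(pred, gt, radius_um=1.0)
        assert corr.gt_to_pred == {}

    def test_small_jitter_fully_matched(self, tiny_scene):
        rng = np.random.default_rng(0)
        jittered = tiny_scene.forest.copy()
        for n in jittered.nodes():
            jittered.graph.nodes[n]["centroid"] = jittered.centroid_of(
                n
            ) + rng.uniform(-0.9, 0.9, 3)
        corr = match_detections(jittered, tiny_scene.forest, radius_um=2.0)
        assert len(corr.gt_to_pred) == len(tiny_scene.forest)


class TestEdgeErrors:
    def test_perfect_prediction_zero_errors(self, tiny_scene):
        f = tiny_scene.forest
        corr = match_detections(f, f, radius_um=1.0)
        rep = edge_error_rate(f, f, corr)
        assert rep.total_errors == 0
        assert rep.error_rate == 0.0
        assert rep.proportion_error_free == 1.0

    def test_one_missed_edge_in_ten(self):
        gt = linear_forest(11)  # 10 edges
        pred = linear_forest(11)
        # break one predicted edge mid-track
        mid = list(pred.nodes())[5]
        pred.graph.remove_edge(pred.parent(mid), mid)
        corr = match_detections(pred, gt, radius_um=0.5)
        rep = edge_error_rate(pred, gt, corr)
        assert rep.n_gt_edges == 10
        assert rep.total_errors == 1
        assert rep.error_rate == pytest.approx(0.1)

    def test_empty_prediction_rate_one(self):
        gt = linear_forest(5)
        rep = edge_error_rate(LineageForest(), gt, match_detections(LineageForest(), gt, 1.0))
        assert rep.error_rate == 1.0

    def test_edgeless_ground_truth_rejected(self):
        gt = LineageForest()
        gt.add_node(0, (0, 0, 0))
        with pytest.raises(ValueError):
            edge_error_rate(gt, gt, match_detections(gt, gt, 1.0))


class TestErrorFreeStats:
    def test_first_error_at_edge_six_gives_length_five(self):
        gt = linear_forest(11)
        pred = linear_forest(11)
        n6 = list(pred.nodes())[6]
        pred.graph.remove_edge(pred.parent(n6), n6)
        corr = match_detections(pred, gt, radius_um=0.5)
        prop, avg = error_free_stats(pred, gt, corr)
        assert prop == 0.0
        assert avg == 5.0

    def test_half_of_tracks_error_free(self):
        gt = LineageForest()
        pred = LineageForest()
        for k, broken in enumerate((False, True)):
            prev_g = prev_p = None
            for t in range(4):
                g = gt.add_node(t, (0.0, 10.0 * k, float(t)))
                p = pred.add_node(t, (0.0, 10.0 * k, float(t)))
                if prev_g is not None:
                    gt.add_edge(prev_g, g)
                    if not (broken and t == 1):
                        pred.add_edge(prev_p, p)
                prev_g, prev_p = g, p
        corr = match_detections(pred, gt, radius_um=0.5)
        prop, avg = error_free_stats(pred, gt, corr)
        assert prop == 0.5
        assert avg == pytest.approx((3 + 0) / 2)

    def test_longest_run_mode(self):
        gt = linear_forest(6)
        pred = linear_forest(6)
        n1 = list(pred.nodes())[1]
        pred.graph.remove_edge(pred.parent(n1), n1)
        corr = match_detections(pred, gt, radius_um=0.5)
        _, prefix_len = error_free_stats(pred, gt, corr, mode="prefix")
        _, run_len = error_free_stats(pred, gt, corr, mode="longest_run")
        assert prefix_len == 0.0
        assert run_len == 4.0


class TestMixingIndex:
    def test_separable_clusters_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, (20, 3))
        b = rng.normal(0, 1, (20, 3)) + 50.0
        assert mixing_index(a, b).index_mean == 0.0

    def test_identical_sets_half(self):
        p = np.random.default_rng(1).normal(size=(12, 3))
        res = mixing_index(p, p)
        assert res.index_mean == pytest.approx(0.5)
        assert res.index_sum == pytest.approx(1.0)

    def test_enumerated_1d_example(self):
        a = np.array([[0.0], [1.0], [2.0]])
        b = np.array([[1.5], [2.5], [3.5]])
        assert mixing_index(a, b).index_mean == pytest.approx(1.0 / 6.0)

    def test_sum_mode_is_twice_mean_here(self):
        a = np.array([[0.0], [1.0], [2.0]])
        b = np.array([[1.5], [2.5], [3.5]])
        res = mixing_index(a, b, mode="sum")
        assert res.index_sum == pytest.approx(1.0 / 3.0)

    def test_rigid_transform_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(2)
        a = rng.normal(size=(25, 3))
        b = rng.normal(loc=0.7, size=(25, 3))
        rot = Rotation.from_euler("xyz", [0.4, -1.1, 2.0]).as_matrix()
        base = mixing_index(a, b).index_mean
        moved = mixing_index(a @ rot.T + 9.0, b @ rot.T + 9.0).index_mean
        assert moved == pytest.approx(base, abs=1e-6)

    def test_degenerate_all_identical_flagged(self):
        p = np.zeros((5, 3))
        res = mixing_index(p, p)
        assert res.degenerate
        assert res.index_mean == 0.5

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            mixing_index(np.zeros((1, 3)), np.ones((5, 3)))


class TestDispersion:
    def test_identical_points_zero(self):
        assert dispersion_index(np.zeros((4, 3))) == 0.0

    def test_unit_square_corners(self):
        corners = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 0], [0, 1, 1]], float)
        assert dispersion_index(corners) == pytest.approx((4 + 2 * np.sqrt(2)) / 6)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            dispersion_index(np.zeros((1, 3)))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        pts=arrays(float, (5, 3), elements=st.floats(-50, 50)),
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-100, 100),
    )
    def test_homogeneity_and_translation_invariance(self, pts, scale, shift):
        base = dispersion_index(pts)
        assert dispersion_index(pts * scale) == pytest.approx(scale * base, rel=1e-9, abs=1e-9)
        assert dispersion_index(pts + shift) == pytest.approx(base, rel=1e-9, abs=1e-6)


class TestVelocity:
    def test_uniform_translation_zero_local_variance(self):
        forests = [linear_forest(5, offset=(0.0, 3.0 * k, 0.0)) for k in range(5)]
        f = LineageForest()
        for sub in forests:
            remap = {}
            for n in sorted(sub.nodes()):
                remap[n] = f.add_node(sub.frame_of(n), sub.centroid_of(n))
            for u, v in sub.edges():
                f.add_edge(remap[u], remap[v])
        vf = velocity_field(f, 2, half_window=1, frame_interval_s=60.0, k=5)
        assert len(vf.nodes) == 5
        np.testing.assert_allclose(vf.velocities_um_min, [[0, 0, 1.0]] * 5, atol=1e-9)
        np.testing.assert_allclose(vf.local_velocity_variance, 0.0, atol=1e-12)

    def test_static_scene_zero_speed(self):
        f = linear_forest(5, speed=0.0)
        vf = velocity_field(f, 2, half_window=2, frame_interval_s=60.0, k=2)
        np.testing.assert_allclose(vf.speeds_um_min, 0.0)

    def test_two_speed_populations(self):
        f = LineageForest()
        for k in range(6):
            speed = 1.0 if k < 3 else 2.0
            y = 5.0 * k
            prev = None
            for t in range(5):
                n = f.add_node(t, (0.0, y, speed * t))
                if prev is not None:
                    f.add_edge(prev, n)
                prev = n
        vf = velocity_field(f, 2, half_window=1, frame_interval_s=60.0, k=3)
        order = np.argsort(vf.positions_um[:, 1])
        slow = vf.local_mean_speed[order[:3]]
        fast = vf.local_mean_speed[order[3:]]
        assert np.all(slow < fast)
        # variance concentrates near the population interface
        inner = vf.local_velocity_variance[order[0]]
        edge = vf.local_velocity_variance[order[2]]
        assert edge >= inner

    def test_one_frame_track_skipped(self):
        f = LineageForest()
        f.add_node(2, (0.0, 0.0, 0.0))
        vf = velocity_field(f, 2, half_window=1, frame_interval_s=60.0, k=2)
        assert vf.nodes == []


class TestExpressionCorrelation:
    def test_copy_and_negation_rank_ends(self):
        rng = np.random.default_rng(0)
        speeds = rng.uniform(1, 5, 30)
        expr = pd.DataFrame(
            {
                f"c{i}": [speeds[i], -speeds[i], rng.normal()]
                for i in range(30)
            },
            index=["copy", "negated", "random"],
        )
        out = expression_velocity_correlation(expr, speeds)
        assert out.index[0] == "copy"
        assert out.loc["copy", "r"] == pytest.approx(1.0)
        assert out.index[-1] == "negated"
        assert out.loc["negated", "r"] == pytest.approx(-1.0)

    def test_planted_correlated_gene_ranks_first(self):
        rng = np.random.default_rng(1)
        speeds = rng.uniform(0, 10, 60)
        planted = 2.0 * speeds + rng.normal(0, 2.0, 60)
        genes = {f"g{i}": rng.normal(5, 2, 60) for i in range(20)}
        genes["planted"] = planted
        expr = pd.DataFrame(genes).T
        out = expression_velocity_correlation(expr, speeds)
        assert out.index[0] == "planted"
        assert out.loc["planted", "r"] > 0.7

    def test_zero_variance_gene_reported_missing(self):
        speeds = np.array([1.0, 2.0, 3.0, 4.0])
        expr = pd.DataFrame({"flat": [5, 5, 5, 5], "ok": [1, 2, 3, 4]}).T
        out = expression_velocity_correlation(expr, speeds)
        assert np.isnan(out.loc["flat", "r"])
        assert out.index[-1] == "flat"

    def test_misaligned_table_rejected(self):
        with pytest.raises(ValueError):
            expression_velocity_correlation(
                pd.DataFrame(np.ones((2, 5))), np.ones(4)
            )


class TestGlobalPointMatching:
    def test_identity_on_same_cloud(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        res = global_point_matching(pts, pts, dummy_cost=10.0)
        assert res.pairs == [(i, i) for i in range(6)]
        assert res.total_cost == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_recovered(self):
        pts = np.random.default_rng(1).normal(size=(8, 3))
        res = global_point_matching(pts, pts + 7.5, dummy_cost=10.0)
        assert res.pairs == [(i, i) for i in range(8)]
        assert res.total_cost < 1e-6

    def test_matches_brute_force_on_permuted_cloud(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(5, 3))
        perm = rng.permutation(5)
        b = a[perm] + rng.normal(scale=0.01, size=(5, 3))
        res = global_point_matching(a, b, dummy_cost=10.0)
        best_cost, best_perm = min(
            (
                sum(((a[i] - res.aligned_b[p[i]]) ** 2).sum() for i in range(5)),
                p,
            )
            for p in itertools.permutations(range(5))
        )
        got = dict(res.pairs)
        assert all(got[i] == best_perm[i] for i in range(5))

    def test_cost_never_exceeds_identity_assignment(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(7, 3))
        b = rng.normal(size=(7, 3))
        res = global_point_matching(a, b, dummy_cost=50.0)
        identity = ((a - res.aligned_b) ** 2).sum()
        assert res.total_cost <= identity + 1e-9

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            global_point_matching(np.zeros((0, 3)), np.zeros((3, 3)), 1.0)


class TestDivisionPR:
    def test_perfect_and_empty(self, standard_scene):
        scene, *_ = standard_scene
        f = scene.forest
        p, r = division_precision_recall(f, f, radius_um=1.0)
        assert p == 1.0 and r == 1.0
        p, r = division_precision_recall(linear_forest(3), f, radius_um=1.0)
        assert r == 0.0
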