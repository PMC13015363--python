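import numpy as np
import pytest

from embryotrack.config import PipelineConfig
from embryotrack.detect import Detection, DetectionSet
from embryotrack.forest import LineageForest
from embryotrack.io import LabelSeries
from embryotrack.lineage import (
    associate_tracklets,
    backtrack_fates,
    detect_divisions,
    stitch_batches,
    tracks_to_forest,
)
from embryotrack.link import Tracklet


def _dets_from_positions(tracks, n_frames):
    """tracks: list of {frame: (z, y, x)} dicts; one detection id per track."""
    labels = LabelSeries([np.zeros((4, 4, 4), np.int32)] * n_frames, (1, 1, 1))
    ds = DetectionSet(labels)
    tracklets = []
    for tid, tr in enumerate(tracks, start=1):
        nodes = []
        for frame in sorted(tr):
            ds.add(
                Detection(
                    id=tid, frame=frame, centroid_um=np.asarray(tr[frame], float),
                    volume_um3=100.0, voxel_count=50, mean_intensity=120.0,
                    z_score=10.0,
                )
            )
            nodes.append((frame, tid))
        tracklets.append(Tracklet(nodes=nodes))
    return ds, tracklets


class TestAssociateTracklets:
    def test_gap_split_track_merged(self):
        # one straight trajectory broken by a missing frame-2 detection
        a = {t: (5.0, 5.0, 5.0 + t) for t in range(0, 2)}
        b = {t: (5.0, 5.0, 5.0 + t) for t in range(3, 6)}
        ds, tracklets = _dets_from_positions([a, b], 6)
        cfg = PipelineConfig(nominal_radius_um=2.0)
        merged = associate_tracklets(tracklets, ds, cfg)
        assert len(merged) == 1
        assert merged[0].start_frame == 0 and merged[0].end_frame == 5

    def test_far_tracklets_not_merged(self):
        a = {t: (5.0, 5.0, 5.0) for t in range(0, 2)}
        b = {t: (5.0, 5.0, 50.0) for t in range(3, 6)}
        ds, tracklets = _dets_from_positions([a, b], 6)
        cfg = PipelineConfig(nominal_radius_um=2.0)
        merged = associate_tracklets(tracklets, ds, cfg)
        assert len(merged) == 2

    def test_gap_beyond_limit_not_merged(self):
        a = {t: (5.0, 5.0, 5.0 + t) for t in range(0, 2)}
        b = {t: (5.0, 5.0, 5.0 + t) for t in range(6, 9)}  # gap of 5 > default 3
        ds, tracklets = _dets_from_positions([a, b], 9)
        cfg = PipelineConfig(nominal_radius_um=2.0)
        assert len(associate_tracklets(tracklets, ds, cfg)) == 2


def _division_forest(parent_len=8, child_len=5, child_vol=50.0, parent_vol=100.0):
    f = LineageForest()
    prev = None
    t_div = parent_len - 1
    for t in range(parent_len):
        n = f.add_node(t, (5.0, 10.0, 10.0 + 0.3 * t), volume=parent_vol)
        if prev is not None:
            f.add_edge(prev, n)
        prev = n
    p_end = prev
    for dy in (-3.0, 3.0):
        cprev = None
        for k in range(child_len):
            n = f.add_node(
                t_div + 1 + k, (5.0, 10.0 + dy, 10.3 + 0.3 * (t_div + k)),
                volume=child_vol,
            )
            if cprev is not None:
                f.add_edge(cprev, n)
            cprev = n
    return f, p_end


class TestDetectDivisions:
    def test_symmetric_division_accepted(self):
        forest, p_end = _division_forest()
        cfg = PipelineConfig(nominal_radius_um=2.75)
        cands = detect_divisions(forest, cfg)
        accepted = [c for c in cands if c.accepted]
        assert len(accepted) == 1
        assert accepted[0].parent_node == p_end
        forest.validate()
        assert len(forest.division_nodes()) == 1

    def test_short_parent_rejected_unless_left_censored(self):
        # parent alive frames 2..4 (len 3 < 5), NOT starting at the scene
        # first frame: rejected
        f = LineageForest()
        anchor = f.add_node(0, (5.0, 50.0, 50.0))  # unrelated cell fixing frame 0
        a2 = f.add_node(1, (5.0, 50.0, 50.0))
        f.add_edge(anchor, a2)
        prev = None
        for t in range(2, 5):
            n = f.add_node(t, (5.0, 10.0, 10.0), volume=100.0)
            if prev is not None:
                f.add_edge(prev, n)
            prev = n
        for dy in (-3.0, 3.0):
            f.add_node(5, (5.0, 10.0 + dy, 10.0), volume=50.0)
        cfg = PipelineConfig(nominal_radius_um=2.75)
        cands = detect_divisions(f, cfg)
        assert not any(c.accepted for c in cands)
        assert any(c.reason == "parent track too short" for c in cands)

    def test_left_censored_parent_passes_length_gate(self):
        forest, _ = _division_forest(parent_len=3)  # root at frame 0
        cfg = PipelineConfig(nominal_radius_um=2.75)
        cands = detect_divisions(forest, cfg)
        assert any(c.accepted for c in cands)

    def test_asymmetric_child_volumes_rejected(self):
        forest, _ = _division_forest(child_vol=50.0)
        # unbalance the daughters strongly
        for n in forest.nodes_at_frame(8):
            forest.graph.nodes[n]["volume"] = (
                10.0 if forest.centroid_of(n)[1] < 10 else 90.0
            )
        cfg = PipelineConfig(nominal_radius_um=2.75)
        cands = detect_divisions(forest, cfg)
        assert not any(c.accepted for c in cands)


class TestStitchBatches:
    def _forest(self, frames, offset=0.0):
        f = LineageForest()
        prev = None
        for t in frames:
            n = f.add_node(t, (5.0, 10.0 + offset, 10.0 + t), volume=100.0)
            if prev is not None:
                f.add_edge(prev, n)
            prev = n
        return f

    def test_matched_overlap_splices_tracks(self):
        a = self._forest(range(0, 8))
        b = self._forest(range(4, 12))
        out = stitch_batches([a, b], overlap=4, gating_radius_um=3.0)
        assert len(out.roots()) == 1
        assert [out.frame_of(n) for n in out.roots()] == [0]
        assert sorted(out.frames()) == list(range(12))

    def test_empty_second_batch_is_identity(self):
        a = self._forest(range(0, 8))
        out = stitch_batches([a, LineageForest()], overlap=4, gating_radius_um=3.0)
        assert out.topology_equal(a)

    def test_shifted_second_batch_beyond_gate_truncates(self):
        a = self._forest(range(0, 8))
        b = self._forest(range(4, 12), offset=50.0)
        out = stitch_batches([a, b], overlap=4, gating_radius_um=3.0)
        # no splice: one track ends at the overlap mid frame, one begins after
        assert len(out.roots()) == 2

    def test_disjoint_batches_rejected(self):
        a = self._forest(range(0, 4))
        b = self._forest(range(8, 12))
        with pytest.raises(ValueError, match="overlap"):
            stitch_batches([a, b], overlap=2, gating_radius_um=3.0)


class TestBacktrackFates:
    def test_without_divisions_ancestors_are_same_tracks(self):
        f = LineageForest()
        tracks = []
        for k in range(3):
            prev = None
            for t in range(5):
                n = f.add_node(t, (5.0, 10.0 * k, 10.0 + t))
                if prev is not None:
                    f.add_edge(prev, n)
                prev = n
            tracks.append(prev)
        clone_map, entered_after = backtrack_fates(f, tracks, 0)
        assert len(clone_map) == 3
        assert entered_after == []
        assert all(len(v) == 1 for v in clone_map.values())

    def test_siblings_share_one_ancestor(self):
        forest, p_end = _division_forest()
        detect_divisions(forest, PipelineConfig(nominal_radius_um=2.75))
        leaves = forest.leaves()
        clone_map, _ = backtrack_fates(forest, leaves, 0)
        assert len(clone_map) == 1
        (descendants,) = clone_map.values()
        assert sorted(descendants) == sorted(leaves)

    def test_cells_entering_after_target_reported(self):
        f = LineageForest()
        n0 = f.add_node(0, (0.0, 0.0, 0.0))
        n1 = f.add_node(1, (0.0, 0.0, 1.0))
        f.add_edge(n0, n1)
        late = f.add_node(1, (0.0, 5.0, 5.0))  # appears at frame 1
        clone_map, entered_after = backtrack_fates(f, [n1, late], 0)
        assert entered_after == [late]
        assert list(clone_map) == [n0]

    def test_full_scene_ancestors_equal_initial_cells(self, standard_scene):
        scene, _, _, _ = standard_scene
        forest = scene.forest
        last = forest.frames()[-1]
        selected = forest.nodes_at_frame(last)
        clone_map, entered_after = backtrack_fates(forest, selected, 0)
        assert entered_after == []
        assert len(clone_map) == len(forest.nodes_at_frame(0))
        assert sum(len(v) for v in clone_map.values()) == len(selected)


class TestTracksToForest:
    def test_gap_interpolation_inserts_flagged_nodes(self):
        a = {t: (5.0, 5.0, 5.0 + t) for t in (0, 1, 4, 5)}
        ds, tracklets = _dets_from_positions([a], 6)
        tracklets[0].gaps = [2, 3]
        forest = tracks_to_forest(tracklets, ds)
        forest.validate()
        interp = [
            n for n in forest.nodes() if forest.graph.nodes[n]["interpolated"]
        ]
        assert [forest.frame_of(n) for n in sorted(interp)] == [2, 3]
        np.testing.assert_allclose(
            forest.centroid_of(interp[0]), [5.0, 5.0, 7.0], atol=1e-9
        )
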