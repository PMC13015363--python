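import numpy as np
import pytest

from embryotrack.config import PipelineConfig
from embryotrack.correct import (
    apply_merge,
    apply_split,
    find_skip_events,
    interpolate_gap,
    iterate_correction,
    redetect_missing,
    GapDescriptor,
)
from embryotrack.detect import detections_from_labels
from embryotrack.io import LabelSeries, VolumeSeries
from embryotrack.link import link_frames
from embryotrack.metrics import count_segmentation_discrepancies
from embryotrack.synthetic import ErrorManifest, inject_errors


def _scene_with_deletion(worked_example):
    scene, _, _, _ = worked_example
    manifest = ErrorManifest(deletes=[scene.forest.graph.nodes[
        scene.forest.nodes_at_frame(9)[0]]["det"]])
    labels, dets = inject_errors(scene, manifest)
    return scene, labels, dets, manifest


class TestSkipEvents:
    def test_no_skip_flow_empty(self, worked_example, worked_example_config):
        scene, _, _, _ = worked_example
        dets = detections_from_labels(scene.series, scene.labels.copy())
        net, sol, _ = link_frames(dets, worked_example_config, strict=True)
        assert find_skip_events(sol, net) == []

    def test_gap_interpolation_linear(self):
        labels = LabelSeries([np.zeros((4, 4, 4), np.int32)] * 3, (1, 1, 1))
        from embryotrack.detect import Detection, DetectionSet

        ds = DetectionSet(labels)
        ds.add(Detection(1, 0, np.array([0.0, 0.0, 0.0]), 100, 10, 100, 10))
        ds.add(Detection(1, 2, np.array([0.0, 0.0, 10.0]), 100, 10, 100, 10))
        gap = GapDescriptor((0, 1), (2, 1), [1], [])
        interpolate_gap(gap, ds)
        np.testing.assert_allclose(gap.positions_um[0], [0, 0, 5])

    def test_two_frame_gap_two_positions(self):
        labels = LabelSeries([np.zeros((4, 4, 4), np.int32)] * 4, (1, 1, 1))
        from embryotrack.detect import Detection, DetectionSet

        ds = DetectionSet(labels)
        ds.add(Detection(1, 0, np.array([0.0, 0.0, 0.0]), 100, 10, 100, 10))
        ds.add(Detection(1, 3, np.array([0.0, 0.0, 9.0]), 100, 10, 100, 10))
        gap = GapDescriptor((0, 1), (3, 1), [1, 2], [])
        interpolate_gap(gap, ds)
        np.testing.assert_allclose(gap.positions_um, [[0, 0, 3], [0, 0, 6]])


class TestRedetect:
    def test_deleted_cell_recovered(self, worked_example, worked_example_config):
        scene, _, _, _ = worked_example
        gt_node = scene.forest.nodes_at_frame(9)[0]
        gt_pos = scene.forest.centroid_of(gt_node)
        manifest = ErrorManifest(deletes=[scene.forest.graph.nodes[gt_node]["det"]])
        _, dets = inject_errors(scene, manifest)
        net, sol, _ = link_frames(
            dets, worked_example_config, strict=True, extent_um=scene.series.extent_um
        )
        gaps = find_skip_events(sol, net)
        assert len(gaps) == 1
        interpolate_gap(gaps[0], dets)
        created = redetect_missing(scene.series, gaps[0], dets, worked_example_config)
        assert len(created) == 1
        assert np.linalg.norm(created[0].centroid_um - gt_pos) <= 2.0

    def test_gap_over_empty_space_returns_nothing(
        self, worked_example, worked_example_config
    ):
        scene, _, _, _ = worked_example
        dets = detections_from_labels(scene.series, scene.labels.copy())
        # a fabricated gap in a region with no cell
        gap = GapDescriptor((8, 1), (10, 1), [9], [np.array([16.0, 46.0, 60.0])])
        created = redetect_missing(scene.series, gap, dets, worked_example_config)
        assert created == []


def _dumbbell_detections():
    shape = (10, 12, 28)
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    lobe_a = ((zz - 5) ** 2 + (yy - 6) ** 2 + (xx - 8) ** 2) <= 16
    lobe_b = ((zz - 5) ** 2 + (yy - 6) ** 2 + (xx - 19) ** 2) <= 16
    neck = (np.abs(zz - 5) <= 1) & (np.abs(yy - 6) <= 1) & (xx > 10) & (xx < 17)
    mask = lobe_a | lobe_b | neck
    vol = np.where(mask, 120.0, 20.0).astype(np.float32)
    labels = np.where(mask, 1, 0).astype(np.int32)
    series = VolumeSeries([vol], (1, 1, 1), 60.0)
    ds = detections_from_labels(series, LabelSeries([labels], (1, 1, 1)))
    return series, ds, lobe_a, lobe_b


class TestApplySplit:
    def test_dumbbell_partitioned_at_neck(self):
        series, ds, lobe_a, lobe_b = _dumbbell_detections()
        cfg = PipelineConfig(nominal_radius_um=4.0)
        before = np.argwhere(ds.labels.frames[0] == 1)
        d0, d1 = apply_split(
            ds, series, 0, 1, (np.array([5.0, 6.0, 8.0]), np.array([5.0, 6.0, 19.0])),
            cfg,
        )
        m0 = ds.labels.frames[0] == d0.id
        m1 = ds.labels.frames[0] == d1.id
        # exact voxel conservation, disjoint, both nonempty
        assert m0.any() and m1.any()
        assert not (m0 & m1).any()
        after = np.argwhere(m0 | m1)
        np.testing.assert_array_equal(before, after)
        # each lobe ends up in one part
        assert (m0 & lobe_a).sum() > 0.9 * lobe_a.sum()
        assert (m1 & lobe_b).sum() > 0.9 * lobe_b.sum()

    def test_coincident_seeds_rejected(self):
        series, ds, *_ = _dumbbell_detections()
        cfg = PipelineConfig(nominal_radius_um=4.0)
        with pytest.raises(ValueError, match="coincide"):
            apply_split(ds, series, 0, 1,
                        (np.array([5.0, 6.0, 8.0]), np.array([5.0, 6.0, 8.0])), cfg)


class TestApplyMerge:
    def _two_cell_detections(self):
        shape = (8, 10, 24)
        labels = np.zeros(shape, np.int32)
        labels[3:6, 4:7, 4:9] = 1  # 45 voxels
        labels[3:6, 4:7, 14:19] = 2
        vol = np.where(labels > 0, 120.0, 20.0).astype(np.float32)
        series = VolumeSeries([vol], (1, 1, 1), 60.0)
        return series, detections_from_labels(series, LabelSeries([labels], (1, 1, 1)))

    def test_volumes_add_and_centroid_weighted(self):
        series, ds = self._two_cell_detections()
        a, b = ds.get(0, 1), ds.get(0, 2)
        va, vb = a.volume_um3, b.volume_um3
        ca, cb = a.centroid_um.copy(), b.centroid_um.copy()
        merged = apply_merge(ds, series, 0, 1, 2)
        assert merged.volume_um3 == pytest.approx(va + vb)
        np.testing.assert_allclose(
            merged.centroid_um, (va * ca + vb * cb) / (va + vb), atol=1e-9
        )
        # old ids retired
        with pytest.raises(KeyError):
            ds.get(0, 1)

    def test_z_score_measured_on_union(self):
        series, ds = self._two_cell_detections()
        merged = apply_merge(ds, series, 0, 1, 2)
        assert np.isfinite(merged.z_score) and merged.z_score > 4


class TestIterateCorrection:
    def test_perfect_input_converges_immediately(
        self, worked_example, worked_example_config
    ):
        scene, _, _, _ = worked_example
        dets = detections_from_labels(scene.series, scene.labels.copy())
        _, _, report = iterate_correction(scene.series, dets, worked_example_config)
        assert report.converged
        assert len(report.iterations) == 1
        assert report.n_accepted == 0

    def test_injected_deletions_recovered(self, worked_example, worked_example_config):
        scene, _, _, _ = worked_example
        nodes = [scene.forest.nodes_at_frame(t)[i] for t, i in ((9, 0), (12, 1), (15, 2))]
        manifest = ErrorManifest(
            deletes=[scene.forest.graph.nodes[n]["det"] for n in nodes]
        )
        _, dets = inject_errors(scene, manifest)
        dets, _, report = iterate_correction(scene.series, dets, worked_example_config)
        assert report.counts()["missing_redetect"] >= 3 * 0.9
        assert count_segmentation_discrepancies(scene.labels, dets.labels)["missing"] == 0

    def test_reproducible_report(self, worked_example, worked_example_config):
        scene, _, corrupted, _ = worked_example
        _, _, r1 = iterate_correction(
            scene.series, corrupted.copy(), worked_example_config
        )
        _, _, r2 = iterate_correction(
            scene.series, corrupted.copy(), worked_example_config
        )
        e1 = [(e.kind, e.frame, e.accepted) for it in r1.iterations for e in it]
        e2 = [(e.kind, e.frame, e.accepted) for it in r2.iterations for e in it]
        assert e1 == e2
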