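import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryotrack.config import PipelineConfig
from embryotrack.detect import (
    detect_frame,
    detect_seeds,
    estimate_noise_sd,
    principal_curvature_score,
    refine_boundaries_mincut,
    region_significance,
)
from embryotrack.synthetic import SimParams, simulate_embryo
from .conftest import gaussian_blob

ISO = (1.0, 1.0, 1.0)


class TestCurvatureScore:
    def test_constant_volume_scores_zero(self):
        assert principal_curvature_score(np.full((10, 20, 20), 50.0), [2.0], ISO).max() == 0.0

    def test_bright_blob_maximum_at_centre(self):
        blob = gaussian_blob(sigma=2.5)
        s = principal_curvature_score(blob, [2.5], ISO)
        assert np.unravel_index(np.argmax(s), s.shape) == (8, 16, 16)

    def test_dark_blob_scores_zero_at_centre(self):
        dark = 100.0 - gaussian_blob(sigma=2.5)
        s = principal_curvature_score(dark, [2.5], ISO)
        assert s[8, 16, 16] == 0.0

    def test_additive_offset_invariance_and_gain_linearity(self):
        blob = gaussian_blob(sigma=2.0)
        s0 = principal_curvature_score(blob, [2.0], ISO)
        s_off = principal_curvature_score(blob + 37.0, [2.0], ISO)
        s_gain = principal_curvature_score(3.0 * blob, [2.0], ISO)
        np.testing.assert_allclose(s_off, s0, atol=1e-4)
        np.testing.assert_allclose(s_gain, 3.0 * s0, rtol=1e-4, atol=1e-4)

    def test_subvoxel_scale_warns(self):
        with pytest.warns(UserWarning, match="below one voxel"):
            principal_curvature_score(np.zeros((4, 8, 8)), [0.5], (2.0, 1.0, 1.0))

    def test_empty_scales_rejected(self):
        with pytest.raises(ValueError):
            principal_curvature_score(np.zeros((4, 4, 4)), [], ISO)


class TestRegionSignificance:
    def _masks(self):
        interior = np.zeros((10, 10, 10), bool)
        shell = np.zeros((10, 10, 10), bool)
        interior[:4, :5, :5] = True  # 100 voxels
        shell[6:, :5, :5] = True  # 100 voxels
        return interior, shell

    def test_closed_form(self):
        interior, shell = self._masks()
        vol = np.zeros((10, 10, 10))
        vol[interior] = 110.0
        vol[shell] = 100.0
        z = region_significance(vol, interior, shell, 5.0)
        assert z == pytest.approx(10.0 / (5.0 * np.sqrt(0.02)), abs=1e-9)
        assert z == pytest.approx(14.142, abs=1e-3)

    def test_equal_means_zero(self):
        interior, shell = self._masks()
        z = region_significance(np.full((10, 10, 10), 7.0), interior, shell, 1.0)
        assert z == 0.0

    def test_monotone_in_interior_intensity(self):
        interior, shell = self._masks()
        vol = np.full((10, 10, 10), 100.0)
        zs = []
        for boost in (0.0, 5.0, 10.0):
            v = vol.copy()
            v[interior] += boost
            zs.append(region_significance(v, interior, shell, 3.0))
        assert zs[0] < zs[1] < zs[2]

    def test_empty_region_rejected(self):
        interior, shell = self._masks()
        with pytest.raises(ValueError):
            region_significance(np.zeros((10, 10, 10)), interior, np.zeros_like(shell), 1.0)
        with pytest.raises(ValueError):
            region_significance(np.zeros((10, 10, 10)), interior, shell, 0.0)


class TestSeeds:
    def test_pure_noise_false_positive_bound(self):
        """At z_thr = 4, pure noise yields <= 1 seed per 1e5 voxels."""
        n_seeds = 0
        n_vox = 0
        for seed in range(10):
            noise = np.maximum(
                np.random.default_rng(seed).normal(100, 10, (32, 64, 64)), 0
            ).astype(np.float32)
            score, smap = principal_curvature_score(
                noise, [2.0, 3.0], ISO, return_scale_map=True
            )
            seeds = detect_seeds(score, noise, 4.0, ISO, scale_map=smap,
                                 default_scale_um=2.0)
            n_seeds += len(seeds)
            n_vox += noise.size
        assert n_seeds / n_vox * 1e5 <= 1.0

    def test_twenty_well_separated_nuclei(self):
        scene = _twenty_cell_scene()
        cfg = PipelineConfig(nominal_radius_um=2.75)
        vol = scene.series.frame(0)
        score, smap = principal_curvature_score(
            vol, cfg.detect.scales_um, scene.series.voxel_size_um, return_scale_map=True
        )
        seeds = detect_seeds(score, vol, 4.0, scene.series.voxel_size_um,
                             scale_map=smap, default_scale_um=2.75)
        gt = np.array([scene.forest.centroid_of(n) for n in scene.forest.nodes_at_frame(0)])
        matched = sum(
            1 for g in gt if min(np.linalg.norm(g - s.centroid_um) for s in seeds) < 2.5
        )
        assert matched == 20

    def test_blob_below_threshold_yields_no_seed(self):
        rng = np.random.default_rng(11)
        vol = rng.normal(100, 10, (16, 32, 32))  # SNR 0.5 blob below
        vol += 5.0 * np.exp(
            -sum((g - c) ** 2 for g, c in zip(np.mgrid[0:16, 0:32, 0:32], (8, 16, 16)))
            / (2 * 2.5**2)
        )
        vol = np.maximum(vol, 0).astype(np.float32)
        score, smap = principal_curvature_score(vol, [2.5], ISO, return_scale_map=True)
        seeds = detect_seeds(score, vol, 4.0, ISO, scale_map=smap, default_scale_um=2.5)
        centre_hits = [
            s for s in seeds if np.linalg.norm(s.centroid_um - [8, 16, 16]) < 3
        ]
        assert not centre_hits


def _ball_mask(shape, center, radius):
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    return sum((g - c) ** 2 for g, c in zip(grids, center)) <= radius**2


def _seed_at(score_shape, vox, scale=2.5):
    from embryotrack.detect import SeedRegion

    return SeedRegion(
        centroid_um=np.asarray(vox, float),
        voxels=np.array([vox]),
        scale_um=scale,
        z_score=10.0,
        score=1.0,
    )


class TestMincutRefinement:
    def test_uniform_ball_recovered(self):
        shape = (16, 24, 24)
        mask = _ball_mask(shape, (8, 12, 12), 5)
        vol = np.where(mask, 120.0, 20.0).astype(np.float32)
        labels = refine_boundaries_mincut(vol, [_seed_at(shape, (8, 12, 12))], ISO,
                                          sigma_g=15.0)
        got = labels == 1
        dice = 2 * (got & mask).sum() / (got.sum() + mask.sum())
        assert dice >= 0.95

    def test_dumbbell_cut_at_neck(self):
        shape = (12, 16, 32)
        lobe_a = _ball_mask(shape, (6, 8, 9), 5)
        lobe_b = _ball_mask(shape, (6, 8, 23), 5)
        neck = np.zeros(shape, bool)
        neck[5:8, 7:10, 12:21] = True
        vol = np.where(lobe_a | lobe_b | neck, 120.0, 20.0).astype(np.float32)
        labels = refine_boundaries_mincut(
            vol, [_seed_at(shape, (6, 8, 9)), _seed_at(shape, (6, 8, 23))], ISO,
            sigma_g=15.0,
        )
        la, lb = labels == 1, labels == 2
        assert la.any() and lb.any()
        assert not (la & lb).any()
        # each lobe dominated by its own label
        assert (la & lobe_a).sum() > 0.8 * lobe_a.sum()
        assert (lb & lobe_b).sum() > 0.8 * lobe_b.sum()
        assert not (la & lobe_b).any()
        assert not (lb & lobe_a).any()

    def test_labels_disjoint_and_seeds_retained(self):
        shape = (12, 16, 32)
        vol = (
            np.where(_ball_mask(shape, (6, 8, 10), 4), 120.0, 20.0)
            + np.where(_ball_mask(shape, (6, 8, 22), 4), 120.0, 0.0)
        ).astype(np.float32)
        seeds = [_seed_at(shape, (6, 8, 10)), _seed_at(shape, (6, 8, 22))]
        labels = refine_boundaries_mincut(vol, seeds, ISO, sigma_g=15.0)
        assert labels[6, 8, 10] == 1
        assert labels[6, 8, 22] == 2

    def test_no_seeds_rejected(self):
        with pytest.raises(ValueError):
            refine_boundaries_mincut(np.zeros((4, 4, 4), np.float32), [], ISO)


def _twenty_cell_scene():
    return simulate_embryo(
        SimParams(
            n_cells_initial=20,
            n_frames=1,
            domain_shape_vox=(24, 96, 96),
            shell_center_um=(-40.0, 48.0, 48.0),
            shell_radius_um=70.0,
            theta_range_deg=(10.0, 35.0),
            seed=3,
        )
    )


class TestDetectFrame:
    def test_twenty_nuclei_detected_with_subvoxel_centroids(self):
        scene = _twenty_cell_scene()
        cfg = PipelineConfig(nominal_radius_um=2.75)
        dets, labels = detect_frame(
            scene.series.frame(0), cfg, scene.series.voxel_size_um
        )
        assert len(dets) == 20
        gt = np.array(
            [scene.forest.centroid_of(n) for n in scene.forest.nodes_at_frame(0)]
        )
        for d in dets:
            assert np.min(np.linalg.norm(gt - d.centroid_um, axis=1)) <= 2.0

    def test_noise_only_frames_mostly_empty(self):
        cfg = PipelineConfig(nominal_radius_um=2.75)
        empty = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            img = rng.poisson(20.0, (24, 96, 96)).astype(np.float32)
            img += rng.normal(0, 18.0, img.shape).astype(np.float32)
            dets, _ = detect_frame(np.maximum(img, 0), cfg, (2.0, 1.0, 1.0))
            empty += len(dets) == 0
        assert empty >= 9  # >= 95% over the long run; 10 fixed seeds here

    def test_touching_nuclei_separated(self, worked_example):
        scene, _, _, _ = worked_example
        # frame 10 holds two sibling pairs at ~7 µm spacing
        cfg = PipelineConfig(nominal_radius_um=3.0)
        dets, _ = detect_frame(scene.series.frame(10), cfg, scene.series.voxel_size_um)
        assert len(dets) == 4

    def test_deterministic(self):
        scene = _twenty_cell_scene()
        cfg = PipelineConfig(nominal_radius_um=2.75)
        d1, l1 = detect_frame(scene.series.frame(0), cfg, scene.series.voxel_size_um)
        d2, l2 = detect_frame(scene.series.frame(0), cfg, scene.series.voxel_size_um)
        np.testing.assert_array_equal(l1, l2)
        assert [d.key for d in d1] == [d.key for d in d2]


@settings(deadline=None, max_examples=10, derandomize=True)
@given(offset=st.floats(0.0, 200.0), gain=st.floats(0.5, 4.0))
def test_score_gain_offset_property(offset, gain):
    blob = gaussian_blob(shape=(10, 16, 16), center=(5, 8, 8), sigma=2.0)
    s0 = principal_curvature_score(blob, [2.0], ISO)
    s1 = principal_curvature_score(gain * blob + offset, [2.0], ISO)
    np.testing.assert_allclose(s1, gain * s0, rtol=1e-3, atol=1e-3)


def test_noise_sd_estimator_tracks_truth():
    rng = np.random.default_rng(0)
    for sd in (5.0, 20.0):
        vol = rng.normal(100.0, sd, (32, 64, 64))
        assert abs(estimate_noise_sd(vol) - sd) / sd < 0.05
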