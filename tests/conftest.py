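import warnings

import numpy as np
import pytest

from embryotrack.config import PipelineConfig
from embryotrack.synthetic import (
    SimParams,
    worked_example_fixture,
    inject_errors,
    sample_manifest,
    simulate_embryo,
)

warnings.filterwarnings("ignore", message=".*below one voxel.*")

# canonical seeds for the session-wide scenes; every test that consumes a
# scene sees the same deterministic instance
SCENE_SEED = 1
MANIFEST_SEED = 2


@pytest.fixture(scope="session")
def worked_example():
    """The canonical two-lineage scene with its ten injected errors."""
    scene, corrupted_labels, corrupted_dets, manifest = worked_example_fixture(0)
    return scene, corrupted_labels, corrupted_dets, manifest


@pytest.fixture(scope="session")
def worked_example_config():
    return PipelineConfig(nominal_radius_um=3.0)


@pytest.fixture(scope="session")
def standard_scene():
    """The 200-cell, 50-frame, SNR-10 scene with 30 injected corruptions."""
    scene = simulate_embryo(SimParams(seed=SCENE_SEED))
    manifest = sample_manifest(scene, 10, 10, 10, seed=MANIFEST_SEED)
    corrupted_labels, corrupted_dets = inject_errors(scene, manifest)
    return scene, corrupted_labels, corrupted_dets, manifest


@pytest.fixture(scope="session")
def standard_config():
    return PipelineConfig(nominal_radius_um=2.75)


@pytest.fixture(scope="session")
def standard_run(standard_scene, standard_config):
    """Whole-scene pipeline result on the standard corrupted scene."""
    from embryotrack.pipeline import run_tracking

    scene, _, corrupted_dets, _ = standard_scene
    return run_tracking(
        scene.series, standard_config, detections=corrupted_dets.copy()
    )


@pytest.fixture(scope="session")
def tiny_scene():
    """Five cells, three frames: cheap substrate for I/O and metric tests."""
    return simulate_embryo(
        SimParams(
            n_cells_initial=5,
            n_frames=3,
            domain_shape_vox=(12, 48, 48),
            shell_center_um=(-50.0, 24.0, 24.0),
            shell_radius_um=70.0,
            theta_range_deg=(8.0, 25.0),
            seed=7,
        )
    )


def gaussian_blob(shape=(16, 32, 32), center=(8, 16, 16), sigma=2.0, peak=100.0):
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return peak * np.exp(-d2 / (2.0 * sigma**2))
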