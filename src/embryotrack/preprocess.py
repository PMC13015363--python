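"""Optional image restoration and motion compensation.

All three operations are opt-in; the default pipeline runs without them.
Deconvolution is Richardson–Lucy with a user-supplied PSF.  Rigid
registration is phase correlation (deterministic and parameter-free).
Motion flow is coarse block matching — a piecewise-constant displacement
grid, trilinearly interpolated when queried — consumed only by the
linking costs, never used to warp the images themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.restoration import richardson_lucy


@dataclass
class FlowField:
    """Coarse displacement field between a frame pair.

    ``centers_um``: (n, 3) block centres; ``vectors_um``: (n, 3)
    displacements, both physical (z, y, x) µm.  ``grid_shape`` is the
    block-grid layout used for interpolation.
    """

    centers_um: np.ndarray
    vectors_um: np.ndarray
    grid_shape: tuple[int, int, int]
    block_size_vox: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vectors_um)):
            raise ValueError("flow vectors must be finite")

    def query(self, position_um, t: int = 0) -> np.ndarray:
        """Trilinearly interpolated displacement at a physical position.

        ``t`` is accepted for interchangeability with :class:`FlowSeries`
        and ignored (a single field covers one frame pair).
        """
        from scipy.interpolate import RegularGridInterpolator

        grid = self.centers_um.reshape(*self.grid_shape, 3)
        axes = [grid[..., a] for a in range(3)]
        coords = [
            np.unique(axes[0][:, 0, 0]),
            np.unique(axes[1][0, :, 0]),
            np.unique(axes[2][0, 0, :]),
        ]
        vecs = self.vectors_um.reshape(*self.grid_shape, 3)
        pos = np.clip(
            np.asarray(position_um, dtype=float),
            [c[0] for c in coords],
            [c[-1] for c in coords],
        )
        out = np.empty(3)
        for a in range(3):
            interp = RegularGridInterpolator(
                coords, vecs[..., a], bounds_error=False, fill_value=None
            )
            out[a] = interp(pos[None])[0]
        return out


def deconvolve(volume: np.ndarray, psf: np.ndarray, iterations: int = 20) -> np.ndarray:
    """Richardson–Lucy deconvolution.

    The PSF must be non-negative and is normalised to unit sum.  Output is
    non-negative and conserves total intensity to within ~1% for objects
    away from the volume border.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    psf = np.asarray(psf, dtype=np.float64)
    if np.any(psf < 0):
        raise ValueError("psf must be non-negative")
    s = psf.sum()
    if s <= 0:
        raise ValueError("psf must have positive mass")
    psf = psf / s
    vol = np.asarray(volume, dtype=np.float64)
    out = richardson_lucy(vol, psf, num_iter=iterations, clip=False)
    return np.maximum(out, 0.0)


def rigid_register(
    reference: np.ndarray, moving: np.ndarray, upsample: int = 1
) -> tuple[np.ndarray, np.ndarray, float]:
    """Translation registration by phase correlation.

    Returns ``(shift, registered, score)`` where ``shift`` (voxels, can be
    subvoxel when ``upsample > 1``) maximises the cross-correlation,
    ``registered`` is ``moving`` shifted by it, and ``score`` is the
    normalised correlation between reference and registered volume — low
    scores (< 0.2) flag unreliable estimates, e.g. on pure noise.
    """
    ref = np.asarray(reference, dtype=np.float64)
    mov = np.asarray(moving, dtype=np.float64)
    if ref.size == 0 or mov.size == 0:
        raise ValueError("empty volume")
    if ref.shape != mov.shape:
        raise ValueError("reference and moving volumes must share a shape")
    reg_shift, _, _ = phase_cross_correlation(
        ref, mov, upsample_factor=upsample, normalization=None
    )
    # report the displacement OF the moving volume relative to the
    # reference; registering applies the opposite
    shift = -np.asarray(reg_shift, dtype=float)
    if upsample <= 1:
        registered = np.roll(mov, tuple(int(s) for s in -shift), axis=(0, 1, 2))
    else:
        registered = ndimage.shift(mov, -shift, order=1, mode="wrap")
    a = ref - ref.mean()
    b = registered - registered.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    score = float((a * b).sum() / denom) if denom > 0 else 0.0
    return np.asarray(shift, dtype=float), registered, score


def estimate_motion_flow(
    vol_t: np.ndarray,
    vol_t1: np.ndarray,
    block_size: int,
    voxel_size_um,
) -> FlowField:
    """Block-matching flow from frame t to frame t+1.

    The volume is tiled into blocks of ``block_size`` voxels per axis
    (clipped to the volume); each block's displacement is found by local
    phase correlation against the same block in the next frame.  Blocks
    with negligible structure get zero displacement.
    """
    a = np.asarray(vol_t, dtype=np.float64)
    b = np.asarray(vol_t1, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("volumes must share a shape")
    if block_size < 4:
        raise ValueError("block_size must be >= 4 voxels")
    if any(block_size > s for s in a.shape):
        raise ValueError("block larger than volume")
    voxel = np.asarray(voxel_size_um, dtype=float)

    n_blocks = tuple(max(1, s // block_size) for s in a.shape)
    centers, vectors = [], []
    sd_floor = 1e-3 * (a.std() + 1e-30)
    for iz in range(n_blocks[0]):
        for iy in range(n_blocks[1]):
            for ix in range(n_blocks[2]):
                lo = np.array([iz, iy, ix]) * block_size
                hi = np.minimum(lo + block_size, a.shape)
                sl = tuple(slice(l, h) for l, h in zip(lo, hi))
                blk_a, blk_b = a[sl], b[sl]
                center_vox = (lo + hi - 1) / 2.0
                centers.append(center_vox * voxel)
                if blk_a.std() <= sd_floor or blk_b.std() <= sd_floor:
                    vectors.append(np.zeros(3))
                    continue
                blk_shift, _, _ = phase_cross_correlation(
                    blk_b, blk_a, upsample_factor=4, normalization=None
                )
                vectors.append(np.asarray(blk_shift) * voxel)
    return FlowField(
        centers_um=np.array(centers),
        vectors_um=np.array(vectors),
        grid_shape=n_blocks,
        block_size_vox=block_size,
    )


class FlowSeries:
    """Per-frame-pair flow fields: ``fields[t]`` maps frame t -> t+1."""

    def __init__(self, fields: dict[int, FlowField]):
        self.fields = fields

    def query(self, position_um, t: int = 0) -> np.ndarray:
        if not self.fields:
            return np.zeros(3)
        if t not in self.fields:
            t = min(self.fields, key=lambda k: abs(k - t))
        return self.fields[t].query(position_um)


def preprocess_series(series, config):
    """Apply the enabled restoration steps; returns a new series.

    Deconvolution uses the PSF volume at ``psf_path`` (TIFF or .npy);
    registration aligns every frame to its predecessor by phase
    correlation (integer shifts).  Returns the input unchanged when
    nothing is enabled.
    """
    import tifffile

    from .io import VolumeSeries

    pp = config.preprocess
    if not (pp.deconvolve.enabled or pp.register.enabled):
        return series
    psf = None
    if pp.deconvolve.enabled:
        if not pp.deconvolve.psf_path:
            raise ValueError("deconvolution enabled but no psf_path given")
        if pp.deconvolve.psf_path.endswith(".npy"):
            psf = np.load(pp.deconvolve.psf_path)
        else:
            psf = tifffile.imread(pp.deconvolve.psf_path)
    frames = []
    prev = None
    for t in range(series.n_frames):
        frame = np.asarray(series.frame(t), dtype=np.float64)
        if psf is not None:
            frame = deconvolve(frame, psf, pp.deconvolve.iterations)
        if pp.register.enabled and prev is not None:
            _, frame, _ = rigid_register(prev, frame)
        frames.append(frame.astype(np.float32))
        prev = frames[-1]
    return VolumeSeries(
        frames,
        series.voxel_size_um,
        series.frame_interval_s,
        time_origin_hpf=series.time_origin_hpf,
    )


def estimate_flow_series(series, block_size: int) -> FlowSeries:
    """Block-matching flow for every consecutive frame pair."""
    fields = {}
    for t in range(series.n_frames - 1):
        fields[t] = estimate_motion_flow(
            series.frame(t), series.frame(t + 1), block_size, series.voxel_size_um
        )
    return FlowSeries(fields)
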