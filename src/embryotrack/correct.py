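"""Iterative error correction.

The current tracking solution is itself the error detector: a frame-skip
arc carrying flow marks a probable missing detection between its
endpoints; a one-frame side-track absorbed by a neighbour marks a
probable over-segmentation; an oversized detection flanked by two
detections in both adjacent frames marks a probable under-segmentation.
Each iteration runs missing-cell redetection first, then segmentation
correction (splits and merges), then re-links; the loop exits when an
iteration accepts no corrections or the iteration cap (default 5) is
reached.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .config import PipelineConfig
from .detect import (
    Detection,
    DetectionSet,
    _measure_label,
    binary_seeded_mincut,
    detect_seeds,
    estimate_noise_sd,
    principal_curvature_score,
    refine_boundaries_mincut,
)
from .io import VolumeSeries
from .link import CirculationNetwork, FlowSolution, Tracklet, link_frames


@dataclass
class GapDescriptor:
    """One skip arc with positive flow: a probable missing cell."""

    a_key: tuple[int, int]
    b_key: tuple[int, int]
    frames: list[int]  # intermediate (skipped) frames
    positions_um: list[np.ndarray]  # interpolated centroid per skipped frame


@dataclass
class CorrectionEvent:
    kind: str  # missing_redetect | split_underseg | merge_overseg
    frame: int
    detection_ids: tuple[int, ...]
    evidence: dict
    accepted: bool


@dataclass
class CorrectionReport:
    iterations: list[list[CorrectionEvent]] = field(default_factory=list)
    converged: bool = False

    def counts(self, iteration: int | None = None) -> dict[str, int]:
        events = (
            [e for it in self.iterations for e in it]
            if iteration is None
            else self.iterations[iteration]
        )
        out = {"missing_redetect": 0, "split_underseg": 0, "merge_overseg": 0}
        for e in events:
            if e.accepted:
                out[e.kind] += 1
        return out

    @property
    def n_accepted(self) -> int:
        return sum(self.counts().values())


# ---------------------------------------------------------------------------
# missing cells


def find_skip_events(
    sol: FlowSolution, net: CirculationNetwork | None = None, flow_field=None
) -> list[GapDescriptor]:
    """Gap descriptors for every skip arc carrying flow.

    Intermediate centroids are linearly interpolated between the skip
    endpoints (plus the motion-flow offset when a flow field is given).
    """
    net = net or sol.network
    out: list[GapDescriptor] = []
    for i, a in enumerate(net.arcs):
        if a.kind != "skip" or sol.flow[i] <= 0:
            continue
        (ta, ia), (tb, ib) = a.meta
        # endpoint centroids are stored in the meta of observation arcs'
        # detections; the caller holds the DetectionSet, so carry keys and
        # let position interpolation use the attached centroids
        out.append(GapDescriptor(a.meta[0], a.meta[1], list(range(ta + 1, tb)), []))
    return out


def interpolate_gap(
    gap: GapDescriptor, dets: DetectionSet, flow_field=None
) -> GapDescriptor:
    a = dets.get(*gap.a_key)
    b = dets.get(*gap.b_key)
    ta, tb = gap.a_key[0], gap.b_key[0]
    positions = []
    for tm in gap.frames:
        f = (tm - ta) / (tb - ta)
        p = a.centroid_um + f * (b.centroid_um - a.centroid_um)
        if flow_field is not None:
            p = p + flow_field.query(a.centroid_um, ta) * (tm - ta)
        positions.append(p)
    gap.positions_um = positions
    return gap


def redetect_missing(
    series: VolumeSeries,
    gap: GapDescriptor,
    dets: DetectionSet,
    config: PipelineConfig,
) -> list[Detection]:
    """Re-run detection with a relaxed threshold inside each gap window.

    The window spans 3 nucleus diameters around the interpolated centroid;
    seeds overlapping existing detections are discarded; the accepted seed
    must lie within the gating radius of the interpolated position and its
    refined mask must pass the volume gates.  Accepted detections are
    written into the label series (background voxels only).
    """
    if not gap.positions_um:
        interpolate_gap(gap, dets)
    created: list[Detection] = []
    voxel = np.asarray(series.voxel_size_um)
    shape = np.asarray(series.shape)
    r = config.nominal_radius_um
    half_um = 3.0 * r  # half-extent: 1.5 nucleus diameters
    z_relax = config.detect.z_threshold * config.correct.redetect_relax
    for tm, pos in zip(gap.frames, gap.positions_um):
        if not 0 <= tm < series.n_frames:
            continue
        vol = np.asarray(series.frame(tm), dtype=np.float32)
        noise_sd = estimate_noise_sd(vol)
        cvox = pos / voxel
        lo = np.maximum(np.floor(cvox - half_um / voxel).astype(int), 0)
        hi = np.minimum(np.ceil(cvox + half_um / voxel).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        win = vol[sl]
        score, scale_map = principal_curvature_score(
            win, config.detect.scales_um, voxel, return_scale_map=True
        )
        seeds = detect_seeds(
            score,
            win,
            z_relax,
            voxel,
            scale_map=scale_map,
            default_scale_um=r,
            noise_sd=noise_sd,
        )
        existing = dets.frame_detections(tm)
        ex_pts = np.array([d.centroid_um for d in existing]) if existing else None
        best = None
        best_d = np.inf
        for s in seeds:
            global_c = s.centroid_um + lo * voxel
            if ex_pts is not None and len(ex_pts):
                if np.min(np.linalg.norm(ex_pts - global_c, axis=1)) < r:
                    continue  # duplicates an existing detection
            d = float(np.linalg.norm(global_c - pos))
            if d <= config.link.gating_radius_um and d < best_d:
                best, best_d = s, d
        if best is None:
            continue
        win_labels = refine_boundaries_mincut(
            win, [best], voxel, sigma_g=config.detect.gradient_sigma
        )
        mask = win_labels == 1
        # a redetection targets a single nucleus: clip the grown region to
        # the seed's own physical neighbourhood so the halo of a close
        # neighbour cannot inflate it
        ax = [
            (np.arange(lo[a], hi[a]) * voxel[a] - (best.centroid_um[a] + lo[a] * voxel[a]))
            for a in range(3)
        ]
        d2 = sum(
            (ax[a][tuple(slice(None) if k == a else None for k in range(3))]) ** 2
            for a in range(3)
        )
        mask &= d2 <= (1.8 * config.nominal_radius_um) ** 2
        # keep the volume convention consistent with the surrounding
        # segmentation: a nucleus is its above-half-peak core
        if mask.any():
            bg = float(np.percentile(win, 20))
            peak = float(win[mask].max())
            mask &= win >= bg + 0.5 * (peak - bg)
        raw_count = int(mask.sum())
        # never steal voxels already owned by another detection; and if the
        # candidate substantially overlaps an existing label it is a
        # duplicate of a (possibly mis-segmented) detection, not a missing
        # cell — leave that site to segmentation correction
        mask &= dets.labels.frames[tm][sl] == 0
        count = int(mask.sum())
        if raw_count > 0 and count < 0.7 * raw_count:
            continue
        v_um3 = count * float(np.prod(voxel))
        if not config.detect.min_volume_um3 <= v_um3 <= config.detect.max_volume_um3:
            continue
        # photometric gate: the recovered cell must resemble the track
        # endpoints it reconnects, not a bright noise cluster — noise
        # maxima that sneak past the relaxed threshold sit far below the
        # endpoints' brightness
        bg_win = float(np.percentile(win, 20))
        endpoint_mean = 0.5 * (
            dets.get(*gap.a_key).mean_intensity + dets.get(*gap.b_key).mean_intensity
        )
        cand_mean = float(win[mask].mean())
        if cand_mean < bg_win + 0.5 * (endpoint_mean - bg_win):
            continue
        new_id = dets.next_id(tm)
        frame_labels = dets.labels.frames[tm]
        region = frame_labels[sl]
        region[mask] = new_id
        frame_labels[sl] = region
        det = _measure_label(vol, frame_labels, new_id, tm, voxel, noise_sd)
        dets.add(det)
        created.append(det)
    return created


# ---------------------------------------------------------------------------
# segmentation conflicts


@dataclass
class SegProposal:
    kind: str  # split_underseg | merge_overseg
    frame: int
    detection_ids: tuple[int, ...]
    seeds_um: tuple | None  # split only: two seed points
    evidence: dict


def _track_maps(tracklets: list[Tracklet]):
    track_of: dict[tuple[int, int], int] = {}
    pos_in: dict[tuple[int, int], int] = {}
    for ti, tr in enumerate(tracklets):
        for k, key in enumerate(tr.nodes):
            track_of[key] = ti
            pos_in[key] = k
    return track_of, pos_in


def find_seg_conflicts(
    sol: FlowSolution,
    dets: DetectionSet,
    tracklets: list[Tracklet],
    config: PipelineConfig,
) -> list[SegProposal]:
    """Split and merge proposals from the local space-time patterns.

    The flow solution localises the *suspects* (one-frame side tracks,
    detections absorbing and emitting side flow), but every acceptance
    test is purely geometric and volumetric — evidence the optimal flow
    cannot change — so the same detections always yield the same
    corrections regardless of how ties in the circulation were resolved
    (this is what makes batched and whole-scene processing agree).

    merge_overseg: two same-frame detections within the gate whose
    combined volume matches the single consistent neighbour found on each
    adjacent frame (the over-segmentation pattern: 1 cell at t-1 and t+1,
    2 detections at t).

    split_underseg: a detection whose volume matches the summed volumes
    of two gate-mates present in *both* adjacent frames and exceeds
    ``underseg_gamma`` times the typical single-cell volume around it
    (the under-segmentation pattern: 2 cells at t-1 and t+1, 1 detection
    at t).
    """
    cc = config.correct
    R = config.link.gating_radius_um
    # a cell moves far less than one inter-cell spacing per frame, so the
    # "same cell, adjacent frame" tests use the strict (tracklet) gate
    R_side = config.link.strict_factor * config.nominal_radius_um
    tau = cc.volume_tolerance
    proposals: list[SegProposal] = []
    proposed_pairs: set[tuple[int, frozenset[int]]] = set()
    proposed_splits: set[tuple[int, int]] = set()

    frames_present = sorted(
        t for t in range(dets.n_frames) if dets.frame_detections(t)
    )

    cache = _FrameCache(dets)

    # splits first: fixing under-segmentation dissolves the spurious
    # over-segmentation patterns that merged frames induce on their
    # neighbours (and vice versa the merge validator re-checks later)
    for t in frames_present:
        for u in dets.frame_detections(t):
            found = validate_split_pattern(dets, t, u.id, config, cache)
            if found is None:
                continue
            seeds, evidence = found
            proposed_splits.add((t, u.id))
            proposals.append(SegProposal("split_underseg", t, (u.id,), seeds, evidence))
    for t in frames_present:
        for v in dets.frame_detections(t):
            found = validate_merge_pattern(dets, t, v.id, config, cache)
            if found is None:
                continue
            u_id, evidence = found
            pair = (t, frozenset((u_id, v.id)))
            if pair in proposed_pairs:
                continue
            if (t, u_id) in proposed_splits or (t, v.id) in proposed_splits:
                continue
            proposed_pairs.add(pair)
            proposals.append(
                SegProposal("merge_overseg", t, (u_id, v.id), None, evidence)
            )
    return proposals


class _FrameCache:
    """Per-frame KD-trees over a frozen detection state."""

    def __init__(self, dets: DetectionSet):
        self.dets = dets
        self._trees: dict[int, tuple[list[Detection], cKDTree] | None] = {}

    def frame(self, t: int):
        if t not in self._trees:
            if not 0 <= t < self.dets.n_frames:
                self._trees[t] = None
            else:
                ds = self.dets.frame_detections(t)
                self._trees[t] = (
                    (ds, cKDTree(np.array([d.centroid_um for d in ds])))
                    if ds
                    else None
                )
        return self._trees[t]


def _neighbours(
    dets: DetectionSet,
    t: int,
    point: np.ndarray,
    radius: float,
    cache: _FrameCache | None = None,
) -> list[Detection]:
    if cache is not None:
        entry = cache.frame(t)
        if entry is None:
            return []
        ds, tree = entry
        out = [ds[i] for i in tree.query_ball_point(point, radius)]
    else:
        if not 0 <= t < dets.n_frames:
            return []
        out = [
            d
            for d in dets.frame_detections(t)
            if float(np.linalg.norm(d.centroid_um - point)) <= radius
        ]
    out.sort(key=lambda d: (float(np.linalg.norm(d.centroid_um - point)), d.id))
    return out


def validate_merge_pattern(
    dets: DetectionSet,
    t: int,
    v_id: int,
    config: PipelineConfig,
    cache: _FrameCache | None = None,
):
    """Over-segmentation test for detection ``v`` against current state.

    Returns ``(partner id, evidence)`` when ``v`` and its nearest
    same-frame partner have exactly one consistent cell on each adjacent
    frame and matching volumes; ``None`` otherwise.
    """
    cc = config.correct
    R = config.link.gating_radius_um
    R_side = config.link.strict_factor * config.nominal_radius_um
    try:
        v = dets.get(t, v_id)
    except KeyError:
        return None
    partners = [
        u for u in _neighbours(dets, t, v.centroid_um, R, cache) if u.id != v_id
    ]
    if not partners:
        return None
    u = partners[0]
    mid = 0.5 * (u.centroid_um + v.centroid_um)
    prev = _neighbours(dets, t - 1, mid, R_side, cache)
    nxt = _neighbours(dets, t + 1, mid, R_side, cache)
    if len(prev) != 1 or len(nxt) != 1:
        return None
    m = 0.5 * (prev[0].volume_um3 + nxt[0].volume_um3)
    if abs((u.volume_um3 + v.volume_um3) - m) > cc.volume_tolerance * m:
        return None
    return u.id, {
        "p": (t - 1, prev[0].id),
        "q": (t + 1, nxt[0].id),
        "vol_sum": u.volume_um3 + v.volume_um3,
        "vol_ref": m,
    }


def validate_split_pattern(
    dets: DetectionSet,
    t: int,
    u_id: int,
    config: PipelineConfig,
    cache: _FrameCache | None = None,
):
    """Under-segmentation test for detection ``u`` against current state.

    Returns ``(seed points, evidence)`` when both adjacent frames hold
    two gate-mates whose summed volumes match ``u`` and ``u`` is oversized
    relative to those singles; ``None`` otherwise.
    """
    cc = config.correct
    R = config.link.gating_radius_um
    tau = cc.volume_tolerance
    try:
        u = dets.get(t, u_id)
    except KeyError:
        return None
    prev2 = _neighbours(dets, t - 1, u.centroid_um, R, cache)[:2]
    next2 = _neighbours(dets, t + 1, u.centroid_um, R, cache)[:2]
    if len(prev2) < 2 or len(next2) < 2:
        return None
    sum_p = prev2[0].volume_um3 + prev2[1].volume_um3
    sum_n = next2[0].volume_um3 + next2[1].volume_um3
    if abs(u.volume_um3 - sum_p) > tau * sum_p:
        return None
    if abs(u.volume_um3 - sum_n) > tau * sum_n:
        return None
    singles = [d.volume_um3 for d in prev2 + next2]
    if u.volume_um3 <= cc.underseg_gamma * float(np.median(singles)):
        return None
    p0, p1 = prev2[0].centroid_um, prev2[1].centroid_um
    q0, q1 = next2[0].centroid_um, next2[1].centroid_um
    if np.linalg.norm(p0 - q0) + np.linalg.norm(p1 - q1) > np.linalg.norm(
        p0 - q1
    ) + np.linalg.norm(p1 - q0):
        q0, q1 = q1, q0
    return (0.5 * (p0 + q0), 0.5 * (p1 + q1)), {
        "volume": u.volume_um3,
        "side_sums": (sum_p, sum_n),
        "single_median": float(np.median(singles)),
    }


# ---------------------------------------------------------------------------
# applying corrections


def apply_split(
    dets: DetectionSet,
    series: VolumeSeries,
    frame: int,
    det_id: int,
    seeds_um: tuple,
    config: PipelineConfig,
) -> tuple[Detection, Detection]:
    """Partition one detection's voxels by a two-seed min-cut.

    The voxel union is preserved exactly; the old detection is retired and
    two new detections replace it.  Disconnected components that contain
    neither seed go to the nearer seed.
    """
    s0, s1 = (np.asarray(s, dtype=float) for s in seeds_um)
    if np.linalg.norm(s0 - s1) < 1e-9:
        raise ValueError("split seeds coincide")
    voxel = np.asarray(dets.labels.voxel_size_um)
    labels = dets.labels.frames[frame]
    mask = labels == det_id
    if not mask.any():
        raise KeyError(f"detection {det_id} absent from frame {frame}")
    idx = np.argwhere(mask)
    pts = idx * voxel

    # project seeds onto the voxel set
    def nearest_vox(s):
        return idx[np.argmin(((pts - s) ** 2).sum(axis=1))]

    v0, v1 = nearest_vox(s0), nearest_vox(s1)
    if np.array_equal(v0, v1):
        raise ValueError("split seeds project to the same voxel")

    from scipy import ndimage

    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub_mask = mask[sl]
    vol = np.asarray(series.frame(frame), dtype=np.float32)
    sub_int = vol[sl]

    comps, n_comps = ndimage.label(sub_mask)
    c0 = comps[tuple(v0 - lo)]
    c1 = comps[tuple(v1 - lo)]
    side0 = np.zeros_like(sub_mask)
    if c0 != c1:
        # the lobes are already disconnected: partition by component,
        # orphan components go to the nearer seed
        for c in range(1, n_comps + 1):
            if c == c0:
                side0 |= comps == c
            elif c != c1:
                cc = np.argwhere(comps == c).mean(axis=0) + lo
                cc_um = cc * voxel
                if np.linalg.norm(cc_um - s0) < np.linalg.norm(cc_um - s1):
                    side0 |= comps == c
    else:
        # single lobe: boundary-driven two-seed min-cut (hard seeds only —
        # both sides are equally bright, the intensity valley decides).
        # Seeds are small balls, not single voxels, so the minimum cut
        # cannot cheat by isolating a lone seed voxel.
        shared = comps == c0
        seed_r = max(0.5 * config.nominal_radius_um, float(voxel.max()))
        grids = np.meshgrid(*[np.arange(s) for s in sub_mask.shape], indexing="ij")

        def seed_ball(v):
            d2b = sum(
                ((g - (v - lo)[a]) * voxel[a]) ** 2 for a, g in enumerate(grids)
            )
            return (d2b <= seed_r**2) & shared

        src = seed_ball(v0)
        snk = seed_ball(v1)
        overlap = src & snk
        src &= ~overlap
        snk &= ~overlap
        if not src.any() or not snk.any():
            src = np.zeros_like(sub_mask)
            snk = np.zeros_like(sub_mask)
            src[tuple(v0 - lo)] = True
            snk[tuple(v1 - lo)] = True
        side0 = binary_seeded_mincut(
            sub_int,
            src,
            snk,
            config.detect.gradient_sigma,
            allowed=shared,
            soft_terminal_weight=0.0,
        )
        side0 &= sub_mask
        # other components: nearer seed wins
        for c in range(1, n_comps + 1):
            if c == c0:
                continue
            cc_um = (np.argwhere(comps == c).mean(axis=0) + lo) * voxel
            if np.linalg.norm(cc_um - s0) < np.linalg.norm(cc_um - s1):
                side0 |= comps == c
    side1 = sub_mask & ~side0
    if not side0.any() or not side1.any():
        # degenerate cut: fall back to the perpendicular-bisector plane
        axis = (s1 - s0) / np.linalg.norm(s1 - s0)
        mid = 0.5 * (s0 + s1)
        side = ((idx * voxel - mid) @ axis) < 0
        side0 = np.zeros_like(sub_mask)
        side0[tuple((idx[side] - lo).T)] = True
        side1 = sub_mask & ~side0

    id0 = dets.next_id(frame)
    id1 = id0 + 1
    region = labels[sl]
    region[side0] = id0
    region[side1] = id1
    labels[sl] = region
    noise_sd = estimate_noise_sd(vol)
    d0 = _measure_label(vol, labels, id0, frame, voxel, noise_sd)
    d1 = _measure_label(vol, labels, id1, frame, voxel, noise_sd)
    dets.remove(frame, det_id)
    dets.add(d0)
    dets.add(d1)
    return d0, d1


def apply_merge(
    dets: DetectionSet, series: VolumeSeries, frame: int, id_a: int, id_b: int
) -> Detection:
    """Union two same-frame detections into one; ids of both are retired."""
    a = dets.get(frame, id_a)
    b = dets.get(frame, id_b)
    if a.frame != b.frame:
        raise ValueError("detections must share a frame")
    labels = dets.labels.frames[frame]
    new_id = dets.next_id(frame)
    labels[(labels == id_a) | (labels == id_b)] = new_id
    vol = np.asarray(series.frame(frame), dtype=np.float32)
    voxel = np.asarray(dets.labels.voxel_size_um)
    det = _measure_label(vol, labels, new_id, frame, voxel, estimate_noise_sd(vol))
    dets.remove(frame, id_a)
    dets.remove(frame, id_b)
    dets.add(det)
    return det


def _voxel_hash(labels: np.ndarray, ids: tuple[int, ...]) -> str:
    mask = np.isin(labels, ids)
    return hashlib.sha1(np.argwhere(mask).tobytes()).hexdigest()


# ---------------------------------------------------------------------------
# the loop


def iterate_correction(
    series: VolumeSeries,
    dets: DetectionSet,
    config: PipelineConfig,
    flow_field=None,
    on_iteration=None,
) -> tuple[DetectionSet, list[Tracklet], CorrectionReport]:
    """Run the full correction loop to convergence.

    Per iteration: strict-gate link -> skip-arc gaps -> missing-cell
    redetection -> segmentation conflicts -> splits/merges -> re-link.
    Stops when an iteration accepts nothing or after
    ``config.correct.max_iterations``.  Returns the corrected detection
    set, the final strict tracklets and the per-iteration report.

    ``on_iteration(index, dets, tracklets)``, if given, is called right
    after each (re-)link and before that iteration's corrections — i.e.
    it observes the state produced by the previous iteration's
    corrections, starting with the uncorrected input.
    """
    report = CorrectionReport()
    extent = series.extent_um
    memo: set[tuple[int, str]] = set()
    corrected: dict[int, np.ndarray] = {}  # per-frame corrected-voxel mask

    tracklets: list[Tracklet] = []
    for it in range(config.correct.max_iterations):
        net, sol, tracklets = link_frames(
            dets, config, strict=True, flow_field=flow_field, extent_um=extent
        )
        if on_iteration is not None:
            on_iteration(it, dets, tracklets)
        events: list[CorrectionEvent] = []

        # 1) missing-cell redetection
        for gap in find_skip_events(sol, net):
            interpolate_gap(gap, dets, flow_field)
            found = redetect_missing(series, gap, dets, config)
            got = {d.frame: d for d in found}
            for tm in gap.frames:
                if tm in got:
                    events.append(
                        CorrectionEvent(
                            "missing_redetect",
                            tm,
                            (got[tm].id,),
                            {"gap": (gap.a_key, gap.b_key)},
                            True,
                        )
                    )
                else:
                    events.append(
                        CorrectionEvent(
                            "missing_redetect",
                            tm,
                            (),
                            {"gap": (gap.a_key, gap.b_key)},
                            False,
                        )
                    )

        # 2) segmentation correction (on the pre-redetection state);
        #    proposals are re-validated against the live state right
        #    before application, since earlier corrections in the same
        #    iteration can dissolve a pattern
        for prop in find_seg_conflicts(sol, dets, tracklets, config):
            # kind-agnostic region memo: once the voxels of a region took
            # part in an accepted correction, the opposite correction can
            # never undo it (prevents split/merge ping-pong at marginal
            # sites)
            key = (prop.frame, _voxel_hash(
                dets.labels.frames[prop.frame], prop.detection_ids
            ))
            if key in memo:
                continue
            region = np.isin(dets.labels.frames[prop.frame], prop.detection_ids)
            done = corrected.get(prop.frame)
            if done is not None and region.any():
                overlap = float((region & done).sum()) / float(region.sum())
                if overlap > 0.3:
                    continue  # this site was already corrected once
            try:
                if prop.kind == "merge_overseg":
                    check = validate_merge_pattern(
                        dets, prop.frame, prop.detection_ids[1], config
                    )
                    if check is None or {check[0], prop.detection_ids[1]} != set(
                        prop.detection_ids
                    ):
                        events.append(
                            CorrectionEvent(
                                prop.kind, prop.frame, prop.detection_ids,
                                {**prop.evidence, "error": "pattern dissolved"},
                                False,
                            )
                        )
                        continue
                    memo.add(key)
                    if prop.frame not in corrected:
                        corrected[prop.frame] = np.zeros_like(region)
                    corrected[prop.frame] |= region
                    merged = apply_merge(
                        dets, series, prop.frame, *prop.detection_ids
                    )
                    events.append(
                        CorrectionEvent(
                            prop.kind, prop.frame, (merged.id,), prop.evidence, True
                        )
                    )
                else:
                    check = validate_split_pattern(
                        dets, prop.frame, prop.detection_ids[0], config
                    )
                    if check is None:
                        events.append(
                            CorrectionEvent(
                                prop.kind, prop.frame, prop.detection_ids,
                                {**prop.evidence, "error": "pattern dissolved"},
                                False,
                            )
                        )
                        continue
                    memo.add(key)
                    if prop.frame not in corrected:
                        corrected[prop.frame] = np.zeros_like(region)
                    corrected[prop.frame] |= region
                    d0, d1 = apply_split(
                        dets, series, prop.frame, prop.detection_ids[0],
                        check[0], config,
                    )
                    events.append(
                        CorrectionEvent(
                            prop.kind, prop.frame, (d0.id, d1.id), prop.evidence, True
                        )
                    )
            except (ValueError, KeyError) as exc:
                events.append(
                    CorrectionEvent(
                        prop.kind,
                        prop.frame,
                        prop.detection_ids,
                        {**prop.evidence, "error": str(exc)},
                        False,
                    )
                )

        report.iterations.append(events)
        if not any(e.accepted for e in events):
            report.converged = True
            break

    _, _, tracklets = link_frames(
        dets, config, strict=True, flow_field=flow_field, extent_um=extent
    )
    return dets, tracklets, report
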