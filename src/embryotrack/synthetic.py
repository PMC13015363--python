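"""Ground-truthed synthetic embryo scenes.

Emulates early-embryo light-sheet recordings: nuclei sit on a spherical
cap (a blastoderm shell), drift tangentially toward the vegetal pole
(epiboly-like flow), jiggle with Brownian motion, occasionally divide
into two half-volume daughters, and are rendered as Gaussian blobs
convolved with a Gaussian PSF over a uniform background, with Poisson
shot noise followed by Gaussian read noise.  Every scene carries its
ground-truth label series and lineage forest, so all tracking modules are
testable without any external data.

An :class:`ErrorManifest` injects the three corruption kinds the
correction loop must fix — deleted detections, over-segmentations (one
nucleus split in two) and under-segmentations (two nuclei merged) — and
is retained as the oracle for correction tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .detect import DetectionSet, detections_from_labels
from .forest import LineageForest
from .io import LabelSeries, VolumeSeries


@dataclass
class SimParams:
    """Scene parameters; defaults are the standard 200-cell test scene."""

    n_cells_initial: int = 200
    n_frames: int = 50
    domain_shape_vox: tuple[int, int, int] = (32, 224, 224)
    voxel_size_um: tuple[float, float, float] = (2.0, 1.0, 1.0)
    frame_interval_s: float = 60.0
    shell_radius_um: float = 80.0
    shell_center_um: tuple[float, float, float] = (-20.0, 112.0, 112.0)
    theta_range_deg: tuple[float, float] = (18.0, 55.0)
    drift_um_per_frame: float = 1.0
    brownian_sigma_um: float = 0.5
    division_prob: float = 0.01
    # daughters cannot re-divide within this many frames of their birth —
    # blastomere cell cycles span many frames, so memoryless re-division
    # would be a biological artifact
    division_refractory_frames: int = 10
    nucleus_radius_um: tuple[float, float] = (2.5, 3.0)
    peak_intensity: float = 200.0
    background: float = 20.0
    psf_sigma_um: tuple[float, float, float] = (1.5, 0.5, 0.5)
    read_noise_snr: float = 10.0  # SNR = (peak - background) / read-noise sd
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.division_prob <= 1.0:
            raise ValueError("division_prob must be in [0, 1]")
        if min(self.nucleus_radius_um) <= 0:
            raise ValueError("nucleus radii must be > 0")
        if self.read_noise_snr <= 0:
            raise ValueError("read_noise_snr must be > 0")

    @property
    def extent_um(self) -> np.ndarray:
        return np.asarray(self.domain_shape_vox) * np.asarray(self.voxel_size_um)

    @property
    def read_noise_sd(self) -> float:
        return (self.peak_intensity - self.background) / self.read_noise_snr


@dataclass
class CellRecord:
    """One cell's life: positions per frame from birth to death."""

    cell_id: int
    birth_frame: int
    parent_id: int | None
    positions: list[np.ndarray] = field(default_factory=list)  # µm (z,y,x)
    radii: list[float] = field(default_factory=list)
    children: tuple[int, int] | None = None  # set when the cell divides

    @property
    def death_frame(self) -> int:
        return self.birth_frame + len(self.positions) - 1


@dataclass
class SyntheticScene:
    series: VolumeSeries
    labels: LabelSeries
    forest: LineageForest
    params: SimParams
    cells: list[CellRecord]
    node_of_det: dict[tuple[int, int], int]  # (frame, label) -> forest node


@dataclass
class ErrorManifest:
    """Injected corruptions; each references a GT (frame, label) node."""

    deletes: list[tuple[int, int]] = field(default_factory=list)
    splits: list[tuple[tuple[int, int], tuple[float, float, float]]] = field(
        default_factory=list
    )  # (node, split-plane normal)
    merges: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.deletes) + len(self.splits) + len(self.merges)

    def corrupted_nodes(self) -> list[tuple[int, int]]:
        nodes = list(self.deletes)
        nodes += [n for n, _ in self.splits]
        for a, b in self.merges:
            nodes += [a, b]
        return nodes

    def validate(self, scene: SyntheticScene) -> None:
        seen = set()
        for node in self.corrupted_nodes():
            if node not in scene.node_of_det:
                raise ValueError(f"manifest references nonexistent node {node}")
            if node in seen:
                raise ValueError(f"node {node} corrupted twice")
            seen.add(node)
        for a, b in self.merges:
            if a[0] != b[0]:
                raise ValueError("merge partners must share a frame")


# ---------------------------------------------------------------------------
# dynamics


def _theta_direction(rel: np.ndarray) -> np.ndarray:
    """Unit tangent of increasing polar angle (toward the vegetal pole).

    ``rel`` is the position relative to the shell centre, axes (z, y, x);
    the pole axis is +z.
    """
    r = np.linalg.norm(rel, axis=-1, keepdims=True)
    vhat = rel / np.maximum(r, 1e-9)
    zhat = np.zeros_like(rel)
    zhat[..., 0] = 1.0
    t = (vhat * vhat[..., :1]) - zhat  # (v.z) v - z
    n = np.linalg.norm(t, axis=-1, keepdims=True)
    return t / np.maximum(n, 1e-9)


def _repel(positions: np.ndarray, min_sep: float, iterations: int = 3) -> np.ndarray:
    """Soft pairwise repulsion: push closer-than-min_sep pairs apart."""
    pos = positions.copy()
    for _ in range(iterations):
        if len(pos) < 2:
            break
        tree = cKDTree(pos)
        pairs = tree.query_pairs(min_sep, output_type="ndarray")
        if len(pairs) == 0:
            break
        shift = np.zeros_like(pos)
        for i, j in pairs:
            d = pos[j] - pos[i]
            dist = np.linalg.norm(d)
            if dist < 1e-9:
                d = np.array([0.0, 0.0, 1e-3])
                dist = 1e-3
            push = 0.5 * (min_sep - dist) * d / dist
            shift[i] -= push
            shift[j] += push
        pos += shift
    return pos


def _initial_positions(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Uniform-in-area placement on the spherical cap, with separation."""
    th0, th1 = np.deg2rad(params.theta_range_deg)
    n = params.n_cells_initial
    c0, c1 = np.cos(th1), np.cos(th0)
    min_sep = 2.0 * max(params.nucleus_radius_um)
    center = np.asarray(params.shell_center_um)
    pts = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 200 * n:
            raise ValueError("domain too small for n_cells_initial")
        cos_t = rng.uniform(c0, c1)
        theta = np.arccos(cos_t)
        phi = rng.uniform(0, 2 * np.pi)
        r = params.shell_radius_um + rng.uniform(-2.0, 2.0)
        p = center + r * np.array(
            [np.cos(theta), np.sin(theta) * np.sin(phi), np.sin(theta) * np.cos(phi)]
        )
        if pts:
            d = np.linalg.norm(np.array(pts) - p, axis=1)
            if d.min() < min_sep:
                continue
        pts.append(p)
    return np.array(pts)


def _simulate_cells(params: SimParams, rng: np.random.Generator) -> list[CellRecord]:
    center = np.asarray(params.shell_center_um)
    margin = 2.0 * max(params.nucleus_radius_um)
    lo = np.full(3, margin)
    hi = params.extent_um - margin
    min_sep = 2.0 * max(params.nucleus_radius_um)
    r_lo, r_hi = params.nucleus_radius_um

    # cells must start inside the rendered domain; re-separate after
    # clamping in case a cap edge was cut off
    pos0 = np.clip(_initial_positions(params, rng), lo, hi)
    pos0 = np.clip(_repel(pos0, min_sep), lo, hi)
    cells: list[CellRecord] = []
    alive: list[int] = []
    for i in range(params.n_cells_initial):
        rec = CellRecord(cell_id=i, birth_frame=0, parent_id=None)
        rec.positions.append(pos0[i])
        rec.radii.append(rng.uniform(r_lo, r_hi))
        cells.append(rec)
        alive.append(i)

    for t in range(1, params.n_frames):
        cur = np.array([cells[i].positions[-1] for i in alive])
        rel = cur - center
        drift = params.drift_um_per_frame * _theta_direction(rel)
        # freeze drift at the cap's vegetal rim so cells stay in the domain
        theta = np.arccos(
            np.clip(rel[:, 0] / np.linalg.norm(rel, axis=1), -1.0, 1.0)
        )
        at_rim = theta >= np.deg2rad(params.theta_range_deg[1])
        drift[at_rim] = 0.0
        nxt = cur + drift + rng.normal(0.0, params.brownian_sigma_um, cur.shape)
        # soft radial restoring toward the shell
        rel2 = nxt - center
        r2 = np.linalg.norm(rel2, axis=1, keepdims=True)
        excess = r2 - params.shell_radius_um
        nxt = nxt - 0.3 * np.clip(excess, -6.0, 6.0) * rel2 / np.maximum(r2, 1e-9) * (
            np.abs(excess) > 4.0
        )
        nxt = _repel(nxt, min_sep)
        nxt = np.clip(nxt, lo, hi)

        # divisions: each alive cell divides with probability division_prob
        # once past its post-birth refractory period
        divide = rng.random(len(alive)) < params.division_prob
        for k, i in enumerate(alive):
            born_of_division = cells[i].parent_id is not None
            if born_of_division and (
                t - cells[i].birth_frame <= params.division_refractory_frames
            ):
                divide[k] = False  # initial cells are at random cycle phases
        new_alive: list[int] = []
        for k, i in enumerate(alive):
            if divide[k] and len(cells) + 2 < 30000:
                parent = cells[i]
                r_par = parent.radii[-1]
                # random tangential split axis
                axis = rng.normal(size=3)
                rel_p = parent.positions[-1] - center
                axis -= axis.dot(rel_p) / max(np.dot(rel_p, rel_p), 1e-9) * rel_p
                norm = np.linalg.norm(axis)
                axis = axis / norm if norm > 1e-9 else np.array([0.0, 1.0, 0.0])
                r_child = r_par / 2.0 ** (1.0 / 3.0)
                ids = (len(cells), len(cells) + 1)
                for s, cid in zip((+1.0, -1.0), ids):
                    child = CellRecord(cell_id=cid, birth_frame=t, parent_id=i)
                    child.positions.append(
                        np.clip(nxt[k] + s * r_par * axis, lo, hi)
                    )
                    child.radii.append(r_child)
                    cells.append(child)
                parent.children = ids
                new_alive.extend(ids)
            else:
                cells[i].positions.append(nxt[k])
                # daughters regrow toward the nominal radius
                r_now = cells[i].radii[-1]
                cells[i].radii.append(r_now + 0.03 * (r_hi - r_now))
                new_alive.append(i)
        alive = new_alive
    return cells


# ---------------------------------------------------------------------------
# rendering


def _render(params: SimParams, cells: list[CellRecord], rng: np.random.Generator):
    shape = tuple(params.domain_shape_vox)
    voxel = np.asarray(params.voxel_size_um)
    psf = np.asarray(params.psf_sigma_um)
    frames_img: list[np.ndarray] = []
    frames_lab: list[np.ndarray] = []
    label_of: list[dict[int, int]] = []  # per frame: cell_id -> label

    for t in range(params.n_frames):
        img = np.full(shape, params.background, dtype=np.float32)
        lab = np.zeros(shape, dtype=np.int32)
        best_d2 = np.full(shape, np.inf, dtype=np.float32)
        present = sorted(
            c.cell_id
            for c in cells
            if c.birth_frame <= t <= c.death_frame
        )
        lmap = {cid: k + 1 for k, cid in enumerate(present)}
        for cid in present:
            cell = cells[cid]
            p = cell.positions[t - cell.birth_frame]
            r = cell.radii[t - cell.birth_frame]
            sig = np.sqrt((r / 1.5) ** 2 + psf**2)  # Gaussian blob (x) Gaussian PSF
            half = np.ceil(4.0 * sig / voxel).astype(int)
            cvox = p / voxel
            lo = np.maximum(np.floor(cvox - half).astype(int), 0)
            hi = np.minimum(np.ceil(cvox + half).astype(int) + 1, shape)
            if np.any(lo >= hi):
                continue
            ax = [np.arange(lo[a], hi[a]) * voxel[a] - p[a] for a in range(3)]
            d2n = sum(
                (ax[a][tuple(slice(None) if k == a else None for k in range(3))] / sig[a])
                ** 2
                for a in range(3)
            )
            blob = np.exp(-0.5 * d2n).astype(np.float32)
            sl = tuple(slice(l, h) for l, h in zip(lo, hi))
            img[sl] += (params.peak_intensity - params.background) * blob
            own = blob >= 0.5  # half-peak ownership
            d2 = sum(
                (ax[a][tuple(slice(None) if k == a else None for k in range(3))]) ** 2
                for a in range(3)
            ).astype(np.float32)
            closer = own & (d2 < best_d2[sl])
            lab[sl][closer] = lmap[cid]
            bd = best_d2[sl]
            bd[closer] = d2[closer]
            best_d2[sl] = bd
        if params.poisson_noise:
            img = rng.poisson(img).astype(np.float32)
        img += rng.normal(0.0, params.read_noise_sd, shape).astype(np.float32)
        np.maximum(img, 0.0, out=img)
        frames_img.append(img)
        frames_lab.append(lab)
        label_of.append(lmap)
    return frames_img, frames_lab, label_of


def _build_forest(
    params: SimParams, cells: list[CellRecord], label_of: list[dict[int, int]]
) -> tuple[LineageForest, dict[tuple[int, int], int]]:
    forest = LineageForest()
    node_of_det: dict[tuple[int, int], int] = {}
    last_node: dict[int, int] = {}
    voxvol = float(np.prod(params.voxel_size_um))
    for t in range(params.n_frames):
        for cid, lbl in label_of[t].items():
            cell = cells[cid]
            k = t - cell.birth_frame
            n = forest.add_node(
                t,
                cell.positions[k],
                volume=4.0 / 3.0 * np.pi * cell.radii[k] ** 3,
                det=(t, lbl),
            )
            node_of_det[(t, lbl)] = n
            if k > 0:
                forest.add_edge(last_node[cid], n)
            elif cell.parent_id is not None:
                forest.add_edge(last_node[cell.parent_id], n)
            last_node[cid] = n
    return forest, node_of_det


def simulate_embryo(params: SimParams) -> SyntheticScene:
    """Generate a full scene: images, GT labels and GT lineage forest.

    Deterministic for a fixed ``params.seed`` (byte-identical volumes and
    forests).
    """
    rng = np.random.default_rng(params.seed)
    cells = _simulate_cells(params, rng)
    frames_img, frames_lab, label_of = _render(params, cells, rng)
    series = VolumeSeries(
        frames_img, params.voxel_size_um, params.frame_interval_s
    )
    labels = LabelSeries(frames_lab, params.voxel_size_um)
    forest, node_of_det = _build_forest(params, cells, label_of)
    return SyntheticScene(series, labels, forest, params, cells, node_of_det)


# ---------------------------------------------------------------------------
# corruption


def inject_errors(
    scene: SyntheticScene, manifest: ErrorManifest
) -> tuple[LabelSeries, DetectionSet]:
    """Apply a corruption manifest to the GT labels.

    ``delete`` removes a label from its frame; ``split`` partitions a
    label by a plane through its centroid; ``merge`` unions two labels.
    The returned detection set is re-measured from the corrupted labels
    against the scene's images.
    """
    manifest.validate(scene)
    labels = scene.labels.copy()
    voxel = np.asarray(labels.voxel_size_um)
    for t, lbl in manifest.deletes:
        frame = labels.frames[t]
        if not np.any(frame == lbl):
            raise ValueError(f"label {lbl} absent from frame {t}")
        frame[frame == lbl] = 0
    for (t, lbl), normal in manifest.splits:
        frame = labels.frames[t]
        idx = np.argwhere(frame == lbl)
        if idx.size == 0:
            raise ValueError(f"label {lbl} absent from frame {t}")
        pts = idx * voxel
        centroid = pts.mean(axis=0)
        side = (pts - centroid) @ np.asarray(normal, dtype=float)
        new_lbl = int(frame.max()) + 1
        upper = idx[side > 0]
        if len(upper) == 0 or len(upper) == len(idx):
            raise ValueError(f"split plane misses label {lbl} in frame {t}")
        frame[tuple(upper.T)] = new_lbl
    for (t, la), (_, lb) in manifest.merges:
        frame = labels.frames[t]
        if not np.any(frame == la) or not np.any(frame == lb):
            raise ValueError(f"merge labels missing from frame {t}")
        frame[frame == lb] = la
    dets = detections_from_labels(scene.series, labels)
    return labels, dets


def sample_manifest(
    scene: SyntheticScene,
    n_delete: int,
    n_split: int,
    n_merge: int,
    seed: int = 0,
    merge_max_dist_um: float = 12.0,
) -> ErrorManifest:
    """Sample a valid random manifest over well-conditioned targets.

    Eligible nodes sit mid-track (parent and single child present), away
    from divisions and from the first/last two frames; at most one
    corruption per cell within a +-2-frame window, so each corruption
    leaves an unambiguous local pattern for the correction loop.
    """
    rng = np.random.default_rng(seed)
    forest = scene.forest
    g = forest.graph

    def eligible(n: int) -> bool:
        t = forest.frame_of(n)
        if not 2 <= t <= scene.params.n_frames - 3:
            return False
        par = forest.parent(n)
        ch = forest.children(n)
        if par is None or len(ch) != 1:
            return False
        if len(forest.children(par)) != 1:  # born of division just now
            return False
        if len(forest.children(ch[0])) != 1 and len(forest.children(ch[0])) != 0:
            return False
        return True

    def window_nodes(n: int, radius: int = 2) -> set[int]:
        out = {n}
        frontier = {n}
        for _ in range(radius):
            nxt = set()
            for m in frontier:
                p = forest.parent(m)
                if p is not None:
                    nxt.add(p)
                nxt.update(forest.children(m))
            out |= nxt
            frontier = nxt
        return out

    taken: set[int] = set()

    def claim(ns: list[int]) -> bool:
        block = set()
        for n in ns:
            block |= window_nodes(n)
        if block & taken:
            return False
        taken.update(block)
        return True

    all_nodes = [n for n in forest.nodes() if eligible(n)]
    rng.shuffle(all_nodes)
    manifest = ErrorManifest()

    # merges need close same-frame pairs
    by_frame: dict[int, list[int]] = {}
    for n in all_nodes:
        by_frame.setdefault(forest.frame_of(n), []).append(n)
    merge_pairs = []
    for t, ns in by_frame.items():
        if len(ns) < 2:
            continue
        pts = np.array([forest.centroid_of(n) for n in ns])
        tree = cKDTree(pts)
        for i, j in tree.query_pairs(merge_max_dist_um):
            merge_pairs.append((ns[i], ns[j]))
    rng.shuffle(merge_pairs)
    for a, b in merge_pairs:
        if len(manifest.merges) >= n_merge:
            break
        if claim([a, b]):
            manifest.merges.append(
                (scene.forest.graph.nodes[a]["det"], scene.forest.graph.nodes[b]["det"])
            )

    pool = iter(all_nodes)
    for n in pool:
        if len(manifest.deletes) >= n_delete:
            break
        if claim([n]):
            manifest.deletes.append(g.nodes[n]["det"])
    for n in pool:
        if len(manifest.splits) >= n_split:
            break
        if claim([n]):
            normal = rng.normal(size=3)
            normal[0] = 0.0  # split in-plane: cleaner two-lobe geometry
            nn = np.linalg.norm(normal)
            normal = normal / nn if nn > 1e-9 else np.array([0.0, 1.0, 0.0])
            manifest.splits.append((g.nodes[n]["det"], tuple(normal)))

    if (
        len(manifest.deletes) < n_delete
        or len(manifest.splits) < n_split
        or len(manifest.merges) < n_merge
    ):
        raise ValueError("could not place the requested number of corruptions")
    manifest.validate(scene)
    return manifest


# ---------------------------------------------------------------------------
# the canonical two-lineage worked example


def two_lineage_scene(seed: int = 0) -> SyntheticScene:
    """Deterministic 20-frame scene of two dividing lineages.

    Two well-separated cells drift slowly, each dividing once (frames 4
    and 6); SNR 10.  Built from a scripted cell table so every position is
    reproducible, then rendered with the standard renderer.
    """
    params = SimParams(
        n_cells_initial=2,
        n_frames=20,
        domain_shape_vox=(16, 96, 72),
        voxel_size_um=(2.0, 1.0, 1.0),
        nucleus_radius_um=(3.0, 3.0),
        division_prob=0.0,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    r = 3.0
    r_child = r / 2.0 ** (1.0 / 3.0)
    drift = np.array([0.0, 0.6, 0.0])

    def straight(start, p0, n, radius):
        return [np.asarray(p0) + k * drift for k in range(n)], [radius] * n

    cells: list[CellRecord] = []
    # lineage A: root cell 0 at (16, 24, 20), divides after frame 4
    for root_id, (y0, x0, t_div) in ((0, (24.0, 22.0, 4)), (1, (64.0, 48.0, 6))):
        p0 = np.array([16.0, y0, x0])
        rec = CellRecord(cell_id=len(cells), birth_frame=0, parent_id=None)
        pos, rad = straight(0, p0, t_div + 1, r)
        rec.positions, rec.radii = pos, rad
        parent_idx = len(cells)
        cells.append(rec)
        ids = []
        for s in (+1.0, -1.0):
            child = CellRecord(
                cell_id=len(cells), birth_frame=t_div + 1, parent_id=parent_idx
            )
            c0 = pos[-1] + drift + np.array([0.0, 0.0, s * 3.5])
            n_rest = params.n_frames - (t_div + 1)
            child.positions = [c0 + k * drift for k in range(n_rest)]
            child.radii = [r_child + 0.03 * k * (r - r_child) for k in range(n_rest)]
            ids.append(child.cell_id)
            cells.append(child)
        rec.children = tuple(ids)

    frames_img, frames_lab, label_of = _render(params, cells, rng)
    series = VolumeSeries(frames_img, params.voxel_size_um, params.frame_interval_s)
    labels = LabelSeries(frames_lab, params.voxel_size_um)
    forest, node_of_det = _build_forest(params, cells, label_of)
    return SyntheticScene(series, labels, forest, params, cells, node_of_det)


def worked_example_fixture(
    seed: int = 0,
) -> tuple[SyntheticScene, LabelSeries, DetectionSet, ErrorManifest]:
    """The canonical worked example: two lineages, ten injected errors.

    Two missing detections, two over-segmentations (a nucleus split in
    two) and six under-segmentations (sibling nuclei merged), placed so
    each error leaves an intact local pattern.  Returns
    ``(scene, corrupted labels, corrupted detections, manifest)``.
    """
    scene = two_lineage_scene(seed)

    def det_of(cell_id: int, frame: int) -> tuple[int, int]:
        cell = scene.cells[cell_id]
        n = scene.forest.nodes_at_frame(frame)
        for node in n:
            d = scene.forest.graph.nodes[node]["det"]
            c = scene.forest.centroid_of(node)
            k = frame - cell.birth_frame
            if np.allclose(c, cell.positions[k]):
                return d
        raise KeyError((cell_id, frame))

    # cells: 0 = root A, (1, 2) its daughters; 3 = root B, (4, 5) its daughters
    a1, a2 = scene.cells[0].children
    b1, b2 = scene.cells[3].children
    ny = (0.0, 1.0, 0.0)
    manifest = ErrorManifest(
        deletes=[det_of(a1, 9), det_of(b2, 13)],
        splits=[(det_of(a2, 11), ny), (det_of(b1, 16), ny)],
        merges=[
            (det_of(a1, 13), det_of(a2, 13)),
            (det_of(a1, 15), det_of(a2, 15)),
            (det_of(a1, 17), det_of(a2, 17)),
            (det_of(b1, 8), det_of(b2, 8)),
            (det_of(b1, 10), det_of(b2, 10)),
            (det_of(b1, 18), det_of(b2, 18)),
        ],
    )
    corrupted_labels, corrupted_dets = inject_errors(scene, manifest)
    return scene, corrupted_labels, corrupted_dets, manifest
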