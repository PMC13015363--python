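"""Evaluation against ground truth and downstream lineage analytics.

Tracking quality is scored on edges: a ground-truth linkage is correct
only when both endpoints are matched to predictions and the predictions
are linked the same way.  Headline numbers are the sum of errors per
ground-truth edge (error rate), the proportion of error-free tracks and
the average error-free track length.  Downstream analytics implement the
fate-mapping toolbox: population mixing indices from a separating
hyperplane, the mean-pairwise-distance dispersion index, migration
velocity maps with local k-neighbourhood statistics, gene-expression /
speed correlation, and globally optimal point-cloud matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .forest import LineageForest
from .io import LabelSeries


@dataclass
class Correspondence:
    """Per-frame one-to-one mapping between GT and predicted nodes."""

    gt_to_pred: dict[int, int]  # forest node ids
    pred_to_gt: dict[int, int]
    radius_um: float


@dataclass
class EdgeErrorReport:
    n_gt_edges: int
    missed_edges: int  # GT edges with an unmatched endpoint
    wrong_target_edges: int  # endpoints matched but linked elsewhere
    false_edges: int  # predicted edges between matched nodes with no GT edge
    proportion_error_free: float
    average_error_free_length: float

    @property
    def total_errors(self) -> int:
        return self.missed_edges + self.wrong_target_edges + self.false_edges

    @property
    def error_rate(self) -> float:
        return self.total_errors / self.n_gt_edges


def match_detections(
    pred: LineageForest, gt: LineageForest, radius_um: float
) -> Correspondence:
    """Frame-wise optimal one-to-one assignment within a match radius."""
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    gt_to_pred: dict[int, int] = {}
    frames = sorted(set(gt.frames()) | set(pred.frames()))
    BIG = 1e9
    for t in frames:
        gn = gt.nodes_at_frame(t)
        pn = pred.nodes_at_frame(t)
        if not gn or not pn:
            continue
        gp = np.array([gt.centroid_of(n) for n in gn])
        pp = np.array([pred.centroid_of(n) for n in pn])
        dist = np.linalg.norm(gp[:, None, :] - pp[None, :, :], axis=2)
        cost = np.where(dist <= radius_um, dist, BIG)
        ri, ci = linear_sum_assignment(cost)
        for i, j in zip(ri, ci):
            if dist[i, j] <= radius_um:
                gt_to_pred[gn[i]] = pn[j]
    pred_to_gt = {v: k for k, v in gt_to_pred.items()}
    return Correspondence(gt_to_pred, pred_to_gt, radius_um)


def edge_error_rate(
    pred: LineageForest, gt: LineageForest, corr: Correspondence
) -> EdgeErrorReport:
    """Sum of linkage errors per ground-truth edge.

    Errors = missed GT edges (an endpoint unmatched), wrong-target GT
    edges (both matched but predictions linked differently) and false
    predicted edges between matched nodes that correspond to no GT edge.
    """
    gt_edges = list(gt.edges())
    if not gt_edges:
        raise ValueError("ground truth has no edges")
    pred_edge_set = set(pred.edges())
    missed = wrong = 0
    for u, v in gt_edges:
        pu = corr.gt_to_pred.get(u)
        pv = corr.gt_to_pred.get(v)
        if pu is None or pv is None:
            missed += 1
        elif (pu, pv) not in pred_edge_set:
            wrong += 1
    gt_edge_set = set(gt_edges)
    false = 0
    for a, b in pred.edges():
        ga = corr.pred_to_gt.get(a)
        gb = corr.pred_to_gt.get(b)
        if ga is not None and gb is not None and (ga, gb) not in gt_edge_set:
            false += 1
    prop, avg = error_free_stats(pred, gt, corr)
    return EdgeErrorReport(
        n_gt_edges=len(gt_edges),
        missed_edges=missed,
        wrong_target_edges=wrong,
        false_edges=false,
        proportion_error_free=prop,
        average_error_free_length=avg,
    )


def error_free_stats(
    pred: LineageForest,
    gt: LineageForest,
    corr: Correspondence,
    mode: str = "prefix",
) -> tuple[float, float]:
    """Proportion of error-free GT tracks and mean error-free length.

    A GT track is a complete root-to-leaf path.  In ``prefix`` mode the
    error-free length counts consecutive correct edges from the track
    start until the first error; in ``longest_run`` mode it is the longest
    correct stretch anywhere along the track.  A track is error-free iff
    every one of its edges is correct.
    """
    pred_edge_set = set(pred.edges())

    def edge_ok(u, v) -> bool:
        pu = corr.gt_to_pred.get(u)
        pv = corr.gt_to_pred.get(v)
        return pu is not None and pv is not None and (pu, pv) in pred_edge_set

    lengths = []
    n_free = 0
    paths = gt.root_to_leaf_paths()
    for path in paths:
        oks = [edge_ok(u, v) for u, v in zip(path, path[1:])]
        if mode == "prefix":
            run = 0
            for ok in oks:
                if not ok:
                    break
                run += 1
        else:
            run = best = 0
            for ok in oks:
                run = run + 1 if ok else 0
                best = max(best, run)
            run = best
        lengths.append(run)
        if all(oks):
            n_free += 1
    if not paths:
        return 1.0, 0.0
    return n_free / len(paths), float(np.mean(lengths))


# ---------------------------------------------------------------------------
# segmentation discrepancy counting (corrupted vs GT labels)


def count_segmentation_discrepancies(
    gt: LabelSeries, pred: LabelSeries
) -> dict[str, int]:
    """Count missing / split / merge events between two label series.

    Built on the voxel-overlap contingency per frame: a GT label with no
    overlapping predicted label is *missing*; a GT label covered by k > 1
    predicted labels (each exclusive to it) contributes k-1 *splits*; a
    predicted label covering k > 1 GT labels contributes k-1 *merges*.
    """
    counts = {"missing": 0, "split": 0, "merge": 0}
    for t in range(len(gt)):
        g = gt.frames[t].ravel()
        p = pred.frames[t].ravel()
        sel = (g > 0) | (p > 0)
        g, p = g[sel], p[sel]
        pairs = np.unique(np.stack([g, p]), axis=1)
        gt_partners: dict[int, set[int]] = {}
        pred_partners: dict[int, set[int]] = {}
        for gl, pl in pairs.T:
            if gl > 0:
                gt_partners.setdefault(int(gl), set())
                if pl > 0:
                    gt_partners[int(gl)].add(int(pl))
            if pl > 0 and gl > 0:
                pred_partners.setdefault(int(pl), set()).add(int(gl))
        for gl, ps in gt_partners.items():
            if not ps:
                counts["missing"] += 1
            elif len(ps) > 1 and all(
                len(pred_partners.get(pl, set())) == 1 for pl in ps
            ):
                counts["split"] += len(ps) - 1
        for pl, gs in pred_partners.items():
            if len(gs) > 1:
                counts["merge"] += len(gs) - 1
    counts["total"] = counts["missing"] + counts["split"] + counts["merge"]
    return counts


def division_precision_recall(
    pred: LineageForest,
    gt: LineageForest,
    radius_um: float,
    frame_tol: int = 1,
) -> tuple[float, float]:
    """Match predicted division nodes to GT divisions by position/frame."""
    gt_divs = [(gt.frame_of(n), gt.centroid_of(n)) for n in gt.division_nodes()]
    pr_divs = [(pred.frame_of(n), pred.centroid_of(n)) for n in pred.division_nodes()]
    if not gt_divs:
        return (1.0 if not pr_divs else 0.0), 1.0
    if not pr_divs:
        return 1.0, 0.0
    used = set()
    tp = 0
    for tf, c in pr_divs:
        best, best_d = None, np.inf
        for k, (tg, cg) in enumerate(gt_divs):
            if k in used or abs(tg - tf) > frame_tol:
                continue
            d = np.linalg.norm(cg - c)
            if d <= radius_um and d < best_d:
                best, best_d = k, d
        if best is not None:
            used.add(best)
            tp += 1
    return tp / len(pr_divs), tp / len(gt_divs)


# ---------------------------------------------------------------------------
# mixing index


@dataclass
class MixingResult:
    normal: np.ndarray
    offset: float
    misclassified_frac_a: float
    misclassified_frac_b: float
    index_mean: float
    index_sum: float
    degenerate: bool = False


def mixing_index(
    points_a: np.ndarray, points_b: np.ndarray, mode: str = "mean"
) -> MixingResult:
    """How intermingled two labelled populations are.

    Fits a max-margin linear classifier (soft-margin SVM, C = 1, on
    jointly centred and isotropically scaled coordinates) to get the
    hyperplane *direction*, then chooses the offset along that direction
    that minimises the index exactly (enumerating all thresholds between
    projected points).  ``mode='mean'`` returns the average of the two
    per-class misclassified fractions; ``mode='sum'`` their sum.
    """
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    A = np.atleast_2d(np.asarray(points_a, dtype=float))
    B = np.atleast_2d(np.asarray(points_b, dtype=float))
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each point set needs at least 2 points")
    X = np.vstack([A, B])
    y = np.concatenate([-np.ones(len(A)), np.ones(len(B))])
    center = X.mean(axis=0)
    scale = np.sqrt(((X - center) ** 2).sum(axis=1).mean())
    if scale < 1e-12:
        return MixingResult(np.zeros(X.shape[1]), 0.0, 0.5, 0.5, 0.5, 1.0, True)
    Xs = (X - center) / scale

    from sklearn.svm import SVC

    try:
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(Xs, y)
        w = clf.coef_.ravel()
    except ValueError:
        w = np.zeros(X.shape[1])
    if np.linalg.norm(w) < 1e-12:
        # identical or inseparable-degenerate sets: fall back to the axis
        # of maximal variance
        d = Xs - Xs.mean(axis=0)
        cov = d.T @ d
        w = np.linalg.eigh(cov)[1][:, -1]
        if np.linalg.norm(w) < 1e-12:
            return MixingResult(w, 0.0, 0.5, 0.5, 0.5, 1.0, True)
    w = w / np.linalg.norm(w)

    proj = Xs @ w
    pa, pb = proj[y < 0], proj[y > 0]
    # enumerate all candidate thresholds (midpoints + outside extremes),
    # in both orientations, minimising the requested index
    cuts = np.unique(proj)
    mids = np.concatenate(
        [[cuts[0] - 1.0], (cuts[:-1] + cuts[1:]) / 2.0, [cuts[-1] + 1.0]]
    )
    best = None
    for sign in (1.0, -1.0):
        qa, qb = sign * pa, sign * pb
        for thr in sign * mids:
            # class A below the threshold, class B above
            fa = float(np.mean(qa >= thr))
            fb = float(np.mean(qb < thr))
            idx = (fa + fb) / 2.0 if mode == "mean" else fa + fb
            key = (idx, -abs(thr))
            if best is None or key < best[0]:
                best = (key, sign, thr, fa, fb)
    _, sign, thr, fa, fb = best
    return MixingResult(
        normal=sign * w,
        offset=float(thr * scale + (sign * w) @ center),
        misclassified_frac_a=fa,
        misclassified_frac_b=fb,
        index_mean=(fa + fb) / 2.0,
        index_sum=fa + fb,
        degenerate=False,
    )


def dispersion_index(points: np.ndarray) -> float:
    """Mean pairwise Euclidean distance (µm) of a point set."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    return float(pdist(pts).mean())


# ---------------------------------------------------------------------------
# velocity


@dataclass
class VelocityField:
    nodes: list[int]
    positions_um: np.ndarray
    velocities_um_min: np.ndarray
    speeds_um_min: np.ndarray
    local_mean_speed: np.ndarray
    local_velocity_variance: np.ndarray  # trace of the k-NN velocity covariance
    k: int


def velocity_field(
    forest: LineageForest,
    t: int,
    half_window: int,
    frame_interval_s: float,
    k: int = 50,
) -> VelocityField:
    """Central-difference migration velocities at frame ``t`` (µm/min).

    Per node the position is followed along its own track ``half_window``
    frames back and forward (one-sided at track ends and across
    divisions); local statistics are computed over the ``k`` nearest
    same-frame neighbours (k clamped to the population).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    nodes = forest.nodes_at_frame(t)
    dt_min = frame_interval_s / 60.0

    def walk(n: int, steps: int, direction: str) -> tuple[int, int]:
        cur, moved = n, 0
        for _ in range(steps):
            if direction == "back":
                nxt = forest.parent(cur)
            else:
                ch = forest.children(cur)
                nxt = ch[0] if len(ch) == 1 else None
            if nxt is None:
                break
            cur = nxt
            moved += 1
        return cur, moved

    keep, vels, poss = [], [], []
    for n in nodes:
        nb, mb = walk(n, half_window, "back")
        nf, mf = walk(n, half_window, "fwd")
        if mb + mf == 0:
            continue  # isolated one-frame track: velocity undefined
        v = (forest.centroid_of(nf) - forest.centroid_of(nb)) / ((mb + mf) * dt_min)
        keep.append(n)
        vels.append(v)
        poss.append(forest.centroid_of(n))
    if not keep:
        return VelocityField([], np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0),
                             np.zeros(0), np.zeros(0), k)
    vels = np.array(vels)
    poss = np.array(poss)
    speeds = np.linalg.norm(vels, axis=1)
    kk = min(k, len(keep))
    tree = cKDTree(poss)
    _, nbrs = tree.query(poss, k=kk)
    nbrs = nbrs.reshape(len(keep), kk)
    local_mean = speeds[nbrs].mean(axis=1)
    local_var = np.empty(len(keep))
    for i in range(len(keep)):
        vv = vels[nbrs[i]]
        local_var[i] = np.trace(np.cov(vv.T)) if kk > 1 else 0.0
    return VelocityField(keep, poss, vels, speeds, local_mean, local_var, kk)


def expression_velocity_correlation(
    expr: pd.DataFrame, speeds: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Pearson correlation of each gene's expression with local speed.

    ``expr`` is genes x cells; columns must align with the ``speeds``
    vector.  Zero-variance genes get NaN and sort last.  Returns a
    DataFrame indexed by gene with columns ``r`` and ``rank`` (descending
    by r).
    """
    speeds = np.asarray(speeds, dtype=float)
    if expr.shape[1] != len(speeds):
        raise ValueError("expression table and speed vector are misaligned")
    if len(speeds) < 3:
        raise ValueError("need at least 3 cells")
    rs = {}
    for gene, row in expr.iterrows():
        x = row.to_numpy(dtype=float)
        if np.std(x) < 1e-15 or np.std(speeds) < 1e-15:
            rs[gene] = np.nan
        else:
            rs[gene] = pearsonr(x, speeds)[0]
    out = pd.DataFrame({"r": pd.Series(rs)})
    out = out.sort_values("r", ascending=False, na_position="last")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# point-cloud matching


@dataclass
class PointMatch:
    pairs: list[tuple[int, int]]
    unmatched_a: list[int]
    unmatched_b: list[int]
    total_cost: float
    aligned_b: np.ndarray


def _similarity_align(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Coarse correspondence-free alignment of b onto a.

    Centroid translation, RMS-radius scaling and principal-axes rotation
    (signs disambiguated by third moments along each axis).
    """
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    sa = np.sqrt((a0**2).sum(axis=1).mean())
    sb = np.sqrt((b0**2).sum(axis=1).mean())
    scale = sa / sb if sb > 1e-12 else 1.0
    b0 = b0 * scale

    def axes(x):
        cov = x.T @ x / len(x)
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1]
        v = vecs[:, order]
        # disambiguate each axis sign by the third moment
        for i in range(v.shape[1]):
            m3 = ((x @ v[:, i]) ** 3).mean()
            if m3 < 0:
                v[:, i] = -v[:, i]
        return v

    va, vb = axes(a0), axes(b0)
    rot = va @ vb.T
    if np.linalg.det(rot) < 0:  # keep it a proper rotation
        vb[:, -1] = -vb[:, -1]
        rot = va @ vb.T
    return (rot @ b0.T).T + ca


def global_point_matching(
    cloud_a: np.ndarray, cloud_b: np.ndarray, dummy_cost: float
) -> PointMatch:
    """Globally optimal assignment between two point clouds.

    After coarse similarity alignment, solves the exact linear assignment
    minimising total squared distance, with a per-point dummy alternative
    of cost ``dummy_cost`` leaving points unmatched.
    """
    a = np.atleast_2d(np.asarray(cloud_a, dtype=float))
    b = np.atleast_2d(np.asarray(cloud_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("point clouds must be non-empty")
    b_al = _similarity_align(a, b) if len(a) > 2 and len(b) > 2 else b
    na, nb = len(a), len(b)
    d2 = ((a[:, None, :] - b_al[None, :, :]) ** 2).sum(axis=2)
    # augmented square matrix with dummy rows/columns
    n = na + nb
    cost = np.full((n, n), 0.0)
    cost[:na, :nb] = d2
    cost[:na, nb:] = dummy_cost
    cost[na:, :nb] = dummy_cost
    ri, ci = linear_sum_assignment(cost)
    pairs, una, unb = [], [], []
    total = 0.0
    for i, j in zip(ri, ci):
        if i < na and j < nb:
            pairs.append((i, j))
            total += d2[i, j]
        elif i < na:
            una.append(i)
            total += dummy_cost
        elif j < nb:
            unb.append(j)
            total += dummy_cost
    return PointMatch(pairs, una, unb, total, b_al)
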