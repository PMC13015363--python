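"""Final lineage assembly.

Corrected high-confidence tracklets are re-associated at the tracklet
level with a relaxed motion gate (the same minimum-cost-circulation model
applied to tracklet endpoints), gaps inside merged tracks are filled with
interpolated virtual nodes, batches are stitched by mutual nearest
neighbours in their overlap, and divisions are detected on the assembled
forest with volume and track-length gates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import PipelineConfig
from .detect import DetectionSet
from .forest import LineageForest
from .link import (
    CirculationNetwork,
    Tracklet,
    solve_circulation,
    transition_cost,
)

_TRACKLET_KEEP_REWARD = -50.0  # observation cost forcing every tracklet to be used


# ---------------------------------------------------------------------------
# tracklet-level association


def associate_tracklets(
    tracklets: list[Tracklet],
    dets: DetectionSet,
    config: PipelineConfig,
) -> list[Tracklet]:
    """Merge tracklets across gaps with relaxed motion tolerance.

    Tracklets become nodes of a second circulation: an arc joins the end
    of tracklet ``i`` to the start of tracklet ``j`` when the frame gap is
    in ``[1, tracklet_gap_max]`` and the endpoint distance is within
    ``gating_radius x gap x relax_factor``; costs are the ordinary
    transition costs of the endpoint detections.  The network is solved
    exactly and chains are spliced into merged tracklets.
    """
    lc = config.lineage
    if not tracklets:
        return []
    net = CirculationNetwork()
    for i in range(len(tracklets)):
        net.add_detection_node((0, i))
    ends = np.array(
        [dets.get(*tr.nodes[-1]).centroid_um for tr in tracklets]
    )
    starts = np.array(
        [dets.get(*tr.nodes[0]).centroid_um for tr in tracklets]
    )
    start_frames = np.array([tr.start_frame for tr in tracklets])
    end_frames = np.array([tr.end_frame for tr in tracklets])
    R_relaxed = config.link.gating_radius_um * lc.relax_factor

    for i, tr in enumerate(tracklets):
        key = (0, i)
        net.add_arc(net.pre[key], net.post[key], 1, _TRACKLET_KEEP_REWARD,
                    "observation", (key, key))
        net.add_arc(net.DUMMY, net.pre[key], 1, config.link.c_border, "appear", (key,))
        net.add_arc(net.post[key], net.DUMMY, 1, config.link.c_border,
                    "disappear", (key,))
    tree = cKDTree(starts)
    for i, tr in enumerate(tracklets):
        for j in tree.query_ball_point(ends[i], R_relaxed * lc.tracklet_gap_max):
            gap = start_frames[j] - end_frames[i]
            if not 1 <= gap <= lc.tracklet_gap_max:
                continue
            a = dets.get(*tracklets[i].nodes[-1])
            b = dets.get(*tracklets[j].nodes[0])
            cost = transition_cost(
                a, b, np.zeros(3), config.link, gating_radius_um=R_relaxed
            )
            net.add_arc(
                net.post[(0, i)], net.pre[(0, j)], 1, cost, "transition",
                ((0, i), (0, j)),
            )
    sol = solve_circulation(net)
    succ: dict[int, int] = {}
    for k, arc in enumerate(net.arcs):
        if arc.kind == "transition" and sol.flow[k] > 0:
            succ[arc.meta[0][1]] = arc.meta[1][1]
    merged: list[Tracklet] = []
    has_pred = set(succ.values())
    for i, tr in enumerate(tracklets):
        if i in has_pred:
            continue
        nodes = list(tr.nodes)
        gaps = list(tr.gaps)
        entry_kind, entry_meta = tr.entry_kind, tr.entry_meta
        cur = i
        last = tr
        while cur in succ:
            nxt = tracklets[succ[cur]]
            gaps.extend(range(nodes[-1][0] + 1, nxt.start_frame))
            nodes.extend(nxt.nodes)
            gaps.extend(nxt.gaps)
            cur = succ[cur]
            last = nxt
        merged.append(
            Tracklet(
                nodes=nodes,
                gaps=sorted(gaps),
                entry_kind=entry_kind,
                exit_kind=last.exit_kind,
                entry_meta=entry_meta,
                exit_meta=last.exit_meta,
            )
        )
    return merged


# ---------------------------------------------------------------------------
# forest construction


def tracks_to_forest(
    tracks: list[Tracklet], dets: DetectionSet, interpolate_gaps: bool = True
) -> LineageForest:
    """Linear forest from merged tracks; gaps become interpolated nodes.

    With ``interpolate_gaps=False`` gap edges join the real detections
    directly (the forest then spans frames non-contiguously — useful for
    scoring raw tracklets where virtual nodes would mask missing
    detections).
    """
    forest = LineageForest()
    for tr in sorted(tracks, key=lambda t: (t.start_frame, t.nodes[0])):
        prev = None
        prev_det = None
        for key in tr.nodes:
            det = dets.get(*key)
            if (
                interpolate_gaps
                and prev_det is not None
                and det.frame > prev_det.frame + 1
            ):
                # fill the gap with interpolated virtual nodes
                t0, t1 = prev_det.frame, det.frame
                for tm in range(t0 + 1, t1):
                    f = (tm - t0) / (t1 - t0)
                    c = prev_det.centroid_um + f * (
                        det.centroid_um - prev_det.centroid_um
                    )
                    v = (1 - f) * prev_det.volume_um3 + f * det.volume_um3
                    n = forest.add_node(tm, c, volume=v, interpolated=True)
                    if prev is not None:
                        forest.add_edge(prev, n)
                    prev = n
            n = forest.add_node(
                det.frame, det.centroid_um, volume=det.volume_um3, det=key
            )
            if prev is not None:
                forest.add_edge(prev, n)
            prev = n
            prev_det = det
    return forest


# ---------------------------------------------------------------------------
# batch stitching


def stitch_batches(
    forests: list[LineageForest],
    overlap: int,
    gating_radius_um: float,
) -> LineageForest:
    """Splice per-batch forests at the middle frame of each overlap.

    Detections in the middle overlap frame are matched across batches by
    mutual nearest neighbour within the gating radius; matched pairs
    splice tracks, unmatched tracks terminate or begin exactly as they did
    in their own batch.  The earlier batch wins conflicting topology.
    """
    if not forests:
        raise ValueError("no forests to stitch")
    out = forests[0].copy()
    for nxt in forests[1:]:
        if len(nxt) == 0:
            continue
        frames_a = out.frames()
        frames_b = nxt.frames()
        lo = max(frames_b[0], min(frames_a[-1], frames_b[0] + 0))
        hi = min(frames_a[-1], frames_b[-1])
        if frames_a[-1] < frames_b[0]:
            raise ValueError("batches do not overlap")
        mid = (frames_b[0] + min(frames_a[-1], frames_b[0] + overlap - 1)) // 2
        a_nodes = [n for n in out.nodes_at_frame(mid)]
        b_nodes = [n for n in nxt.nodes_at_frame(mid)]

        # mutual nearest neighbour within the gate
        match: dict[int, int] = {}
        if a_nodes and b_nodes:
            pa = np.array([out.centroid_of(n) for n in a_nodes])
            pb = np.array([nxt.centroid_of(n) for n in b_nodes])
            ta = cKDTree(pa)
            tb = cKDTree(pb)
            da, ia = tb.query(pa)
            db, ib = ta.query(pb)
            for k, n in enumerate(a_nodes):
                j = ia[k]
                if da[k] <= gating_radius_um and ib[j] == k:
                    match[b_nodes[j]] = n

        # drop out's nodes beyond mid (they belong to the overlap tail)
        for n in [n for n in out.nodes() if out.frame_of(n) > mid]:
            out.graph.remove_node(n)
        # import nxt's nodes beyond mid
        imported: dict[int, int] = {}
        for n in sorted(nxt.nodes(), key=lambda m: (nxt.frame_of(m), m)):
            if nxt.frame_of(n) <= mid:
                continue
            imported[n] = out.add_node(
                nxt.frame_of(n),
                nxt.centroid_of(n),
                volume=nxt.volume_of(n),
                interpolated=nxt.graph.nodes[n].get("interpolated", False),
                det=None,
            )
        for u, v in nxt.edges():
            tu, tv = nxt.frame_of(u), nxt.frame_of(v)
            if tu > mid and tv > mid:
                out.add_edge(imported[u], imported[v])
            elif tu == mid and tv == mid + 1 and u in match:
                out.add_edge(match[u], imported[v])
            elif tu == mid and tv == mid + 1:
                pass  # unmatched: the child starts a new track
    out.validate()
    return out


# ---------------------------------------------------------------------------
# division detection


@dataclass
class DivisionCandidate:
    parent_node: int
    child_node: int
    sibling_node: int | None
    accepted: bool
    reason: str


def detect_divisions(
    forest: LineageForest,
    config: PipelineConfig,
) -> list[DivisionCandidate]:
    """Attach division edges to the assembled forest.

    A track starting at frame ``t > 0`` is a division child candidate; its
    candidate parent is the nearest node at ``t - 1`` with spare
    out-degree.  Acceptance gates: parent chain length (back to the
    previous division or root) at least ``division_min_parent_len``; both
    children's volumes within ``division_child_volume_frac`` of the
    parent's; the two children are the parent's two nearest next-frame
    nodes (mutual nearest).  Rejected candidates are reported so the
    caller can route them back to segmentation correction.
    """
    lc = config.lineage
    R = config.link.gating_radius_um * lc.relax_factor
    vmin, vmax = lc.division_child_volume_frac
    candidates: list[DivisionCandidate] = []

    # geometric queries run over real (non-interpolated) nodes only
    by_frame = {
        t: [
            n
            for n in forest.nodes_at_frame(t)
            if not forest.graph.nodes[n].get("interpolated", False)
        ]
        for t in forest.frames()
    }
    trees = {
        t: cKDTree(np.array([forest.centroid_of(n) for n in ns]))
        for t, ns in by_frame.items()
        if ns
    }
    first_frame = min(by_frame) if by_frame else 0

    def chain_len_back(n: int) -> int:
        """Frames since the parent's track began (previous division/root).

        Tracks already present at the scene's first frame are
        left-censored — the cell existed before recording started — and
        always pass the length gate.
        """
        length = 1
        cur = n
        while True:
            p = forest.parent(cur)
            if p is None or len(forest.children(p)) != 1:
                if p is None and forest.frame_of(cur) == first_frame:
                    return max(length, lc.division_min_parent_len)
                break
            cur = p
            length += 1
        return length

    # candidate children: track roots, plus nodes reached only through an
    # interpolated gap bridge (the relaxed association may have bridged an
    # ended track onto a daughter; a fitting division pattern wins the
    # competition and the bridge is cut)
    candidates_in: list[int] = list(forest.roots())
    for n in forest.nodes():
        p = forest.parent(n)
        if (
            p is not None
            and forest.graph.nodes[p].get("interpolated", False)
            and not forest.graph.nodes[n].get("interpolated", False)
        ):
            candidates_in.append(n)

    for r in sorted(set(candidates_in), key=lambda n: (forest.frame_of(n), n)):
        t = forest.frame_of(r)
        if t <= first_frame:
            continue
        if (t - 1) not in trees:
            continue
        bridge_parent = forest.parent(r)
        prev_nodes = by_frame[t - 1]
        kq = min(3, len(prev_nodes))
        dists, idxs = trees[t - 1].query(forest.centroid_of(r), k=kq)
        dists = np.atleast_1d(dists)
        idxs = np.atleast_1d(idxs)

        first_reject: DivisionCandidate | None = None
        accepted = False
        for d, i in zip(dists, idxs):
            p = prev_nodes[int(i)]
            if d > R or len(forest.children(p)) >= 2:
                verdict = DivisionCandidate(p, r, None, False, "no parent in gate")
            else:
                verdict = _judge_division(
                    forest, p, r, t, by_frame, trees, chain_len_back, lc, R,
                    vmin, vmax,
                )
            if verdict.accepted:
                if bridge_parent is not None:
                    _cut_bridge(forest, r)
                forest.add_edge(p, r)
                if forest.parent(verdict.sibling_node) is None:
                    forest.add_edge(p, verdict.sibling_node)
                candidates.append(verdict)
                accepted = True
                break
            if first_reject is None:
                first_reject = verdict
        if not accepted and first_reject is not None:
            candidates.append(first_reject)
    return candidates


def _judge_division(
    forest, p, r, t, by_frame, trees, chain_len_back, lc, R, vmin, vmax
) -> DivisionCandidate:
    """Apply the division gates to one (parent, orphan-child) pair."""
    # sibling: the parent's existing continuation, or another new root
    sib = forest.children(p)[0] if forest.children(p) else None
    if sib is None:
        cur_nodes = [n for n in by_frame[t] if n != r]
        if cur_nodes:
            pts = np.array([forest.centroid_of(n) for n in cur_nodes])
            d2, i2 = cKDTree(pts).query(forest.centroid_of(p))
            cand = cur_nodes[int(i2)]
            if (
                d2 <= R
                and forest.parent(cand) is None
                and len(forest.children(cand)) <= 1
            ):
                sib = cand
    if sib is None:
        return DivisionCandidate(p, r, None, False, "no sibling")
    if chain_len_back(p) < lc.division_min_parent_len:
        return DivisionCandidate(p, r, sib, False, "parent track too short")
    # daughters sit roughly symmetrically about a real parent
    d_r = float(np.linalg.norm(forest.centroid_of(r) - forest.centroid_of(p)))
    d_s = float(np.linalg.norm(forest.centroid_of(sib) - forest.centroid_of(p)))
    if max(d_r, d_s) > 3.0 * max(min(d_r, d_s), 0.5):
        return DivisionCandidate(p, r, sib, False, "asymmetric displacement")
    # symmetric-split prior on each child's share of the combined daughter
    # volume (robust to the PSF compressing apparent sizes), plus a sanity
    # band tying the daughters' total to the parent
    vp = forest.volume_of(p)
    v1, v2 = forest.volume_of(r), forest.volume_of(sib)
    tot = v1 + v2
    ok_vol = (
        vp > 0
        and tot > 0
        and vmin <= v1 / tot <= vmax
        and vmin <= v2 / tot <= vmax
        and 0.5 * vp <= tot <= 2.0 * vp
    )
    if not ok_vol:
        return DivisionCandidate(p, r, sib, False, "child volume outside gate")
    # the pair must be the parent's two nearest next-frame nodes
    k = min(2, len(by_frame[t]))
    _, nearest = trees[t].query(forest.centroid_of(p), k=k)
    nearest_nodes = {by_frame[t][int(j)] for j in np.atleast_1d(nearest)}
    if nearest_nodes != {r, sib}:
        return DivisionCandidate(p, r, sib, False, "children not mutual nearest")
    # over-segmentation mimic: a child that instantly re-merges
    if not forest.children(r) and forest.frame_of(r) < max(by_frame):
        return DivisionCandidate(p, r, sib, False, "child track dies immediately")
    return DivisionCandidate(p, r, sib, True, "accepted")


def _cut_bridge(forest: LineageForest, node: int) -> None:
    """Remove the interpolated gap-bridge feeding ``node``.

    Cuts the incoming edge and deletes the now-dangling chain of
    interpolated ancestors, so the bridging track simply ends at its last
    real node.
    """
    p = forest.parent(node)
    forest.graph.remove_edge(p, node)
    while (
        p is not None
        and forest.graph.nodes[p].get("interpolated", False)
        and forest.graph.out_degree(p) == 0
    ):
        gp = forest.parent(p)
        forest.graph.remove_node(p)
        p = gp


# ---------------------------------------------------------------------------
# fate mapping


def backtrack_fates(
    forest: LineageForest, selected: list[int], t_target: int
) -> tuple[dict[int, list[int]], list[int]]:
    """Trace selected nodes back to their ancestors at ``t_target``.

    Returns ``(clone_map, entered_after)``: ``clone_map`` maps each
    ancestor node at ``t_target`` to the selected descendants it gave rise
    to; ``entered_after`` lists selected nodes whose path begins after the
    target frame (cells that entered the scene later) — reported, not an
    error.
    """
    clone_map: dict[int, list[int]] = {}
    entered_after: list[int] = []
    for n in selected:
        if forest.frame_of(n) < t_target:
            raise ValueError(f"selected node {n} is before t_target")
        cur = n
        while forest.frame_of(cur) > t_target:
            p = forest.parent(cur)
            if p is None:
                break
            cur = p
        if forest.frame_of(cur) == t_target:
            clone_map.setdefault(cur, []).append(n)
        else:
            entered_after.append(n)
    return clone_map, entered_after
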