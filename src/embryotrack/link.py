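"""Global data association as a minimum-cost circulation.

Every detection contributes a *pre* and a *post* node joined by an
observation arc whose (negative, for confident detections) cost rewards
explaining the detection; a single dummy node closes all tracks into
circulations.  Transition arcs connect detections in nearby frames,
frame-skip arcs bridge gaps up to ``g_max`` frames, and discounted
dummy arcs realise one-to-two (division/over-segmentation) and two-to-one
(merge/under-segmentation) matchings.  One unit of circulating flow is one
cell track; the optimum of the network is the maximum-a-posteriori track
decomposition under the cost model.

The solver is exact: the network LP (totally unimodular) is solved with
HiGHS on integer-scaled costs and verified integral, with an exact
network-simplex fallback.  A brute-force dynamic program over all feasible
track decompositions serves as the independent oracle on small instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import sparse
from scipy.optimize import linprog
from scipy.spatial import cKDTree

from .config import LinkConfig, PipelineConfig
from .detect import Detection, DetectionSet

COST_SCALE = 10**6  # float costs -> integer costs for exact arithmetic

ARC_KINDS = (
    "observation",
    "transition",
    "skip",
    "appear",
    "disappear",
    "div_child",
    "merge_parent",
)


@dataclass
class Arc:
    tail: int
    head: int
    cap: int
    cost: int  # integer, scaled by COST_SCALE
    kind: str
    # detection keys (frame, id); semantics depend on kind:
    #  observation: (key, key); transition/skip: (tail key, head key)
    #  appear/disappear: (key,); div_child: (parent key, child key)
    #  merge_parent: (ending key, absorbing key)
    meta: tuple = ()


class CirculationNetwork:
    """Arc list + node index for one linking instance."""

    def __init__(self) -> None:
        self.arcs: list[Arc] = []
        self.pre: dict[tuple[int, int], int] = {}
        self.post: dict[tuple[int, int], int] = {}
        self.n_nodes = 1  # node 0 is the dummy
        self.frame_span: tuple[int, int] = (0, 0)

    DUMMY = 0

    def add_detection_node(self, key: tuple[int, int]) -> None:
        self.pre[key] = self.n_nodes
        self.post[key] = self.n_nodes + 1
        self.n_nodes += 2

    def add_arc(self, tail, head, cap, cost_float, kind, meta=()) -> None:
        if not math.isfinite(cost_float):
            return  # gated out
        self.arcs.append(
            Arc(tail, head, int(cap), int(round(cost_float * COST_SCALE)), kind, meta)
        )

    def arcs_of_kind(self, kind: str) -> list[tuple[int, Arc]]:
        return [(i, a) for i, a in enumerate(self.arcs) if a.kind == kind]


@dataclass
class FlowSolution:
    """Integral optimal circulation."""

    flow: np.ndarray  # per-arc integer flow
    total_cost_scaled: int
    network: CirculationNetwork

    @property
    def total_cost(self) -> float:
        return self.total_cost_scaled / COST_SCALE

    def flow_on(self, arc_index: int) -> int:
        return int(self.flow[arc_index])


@dataclass
class Tracklet:
    """A high-confidence track fragment: ordered (frame, detection id)."""

    nodes: list[tuple[int, int]]
    gaps: list[int] = field(default_factory=list)  # frames skipped inside
    confidence: float = 1.0
    entry_kind: str = "appear"
    exit_kind: str = "disappear"
    entry_meta: tuple = ()
    exit_meta: tuple = ()

    @property
    def start_frame(self) -> int:
        return self.nodes[0][0]

    @property
    def end_frame(self) -> int:
        return self.nodes[-1][0]

    def __len__(self) -> int:
        return len(self.nodes)


# ---------------------------------------------------------------------------
# costs


def transition_cost(
    a: Detection,
    b: Detection,
    flow_offset_um: np.ndarray,
    params: LinkConfig,
    gating_radius_um: float | None = None,
) -> float:
    """Cost of linking detection ``a`` (frame t) to ``b`` (frame t+gap).

    ``d^2 / (2 sigma_m^2) + w_v * log(vol_b / vol_a)^2 + (gap-1) * C_skip``
    with ``d`` the distance from b to a's flow-predicted position.
    Returns ``inf`` (arc omitted) beyond the gate ``R * gap``.
    """
    gap = b.frame - a.frame
    if gap < 1:
        raise ValueError("b must be in a later frame than a")
    R = params.gating_radius_um if gating_radius_um is None else gating_radius_um
    d = float(np.linalg.norm(b.centroid_um - (a.centroid_um + flow_offset_um)))
    if d > R * gap:
        return math.inf
    vol_term = params.volume_weight * math.log(b.volume_um3 / a.volume_um3) ** 2
    return d * d / (2.0 * params.sigma_motion_um**2) + vol_term + (gap - 1) * params.c_skip


def detection_cost(det: Detection, z_thr: float) -> float:
    """Observation-arc cost ``-log(p / (1 - p))`` with ``p = logistic(z - z_thr)``."""
    p = 1.0 / (1.0 + math.exp(-(det.z_score - z_thr)))
    p = min(max(p, 1e-3), 1.0 - 1e-3)
    return -math.log(p / (1.0 - p))


# ---------------------------------------------------------------------------
# network construction


def build_circulation(
    dets: DetectionSet,
    params: LinkConfig,
    z_thr: float = 4.0,
    flow_field=None,
    frame_range: tuple[int, int] | None = None,
    gating_radius_um: float | None = None,
    border_margin_um: float = 0.0,
    extent_um: tuple[float, float, float] | None = None,
) -> CirculationNetwork:
    """Build the circulation network over ``dets``.

    Appear/disappear costs are ``C_border``, discounted 4x at the first /
    last frame of the span and within ``border_margin_um`` of the volume
    border (cells legitimately enter and leave there).  Division-child and
    merge-parent dummy arcs are added for the ``knn_div`` nearest
    neighbours in the adjacent frame whose geometry is
    division-consistent.  ``flow_field`` (optional) supplies the motion
    offset used by :func:`transition_cost`.
    """
    net = CirculationNetwork()
    if frame_range is None:
        frames_present = sorted(
            t for t in range(dets.n_frames) if dets.frame_detections(t)
        )
        if not frames_present:
            net.frame_span = (0, 0)
            return net
        frame_range = (frames_present[0], frames_present[-1])
    t0, t1 = frame_range
    net.frame_span = (t0, t1)
    R = params.gating_radius_um if gating_radius_um is None else gating_radius_um

    frames = {t: dets.frame_detections(t) for t in range(t0, t1 + 1)}
    for t in range(t0, t1 + 1):
        for det in frames[t]:
            net.add_detection_node(det.key)

    def near_border(det: Detection) -> bool:
        if border_margin_um <= 0 or extent_um is None:
            return False
        c = det.centroid_um
        ext = np.asarray(extent_um)
        return bool(np.any(c < border_margin_um) or np.any(ext - c < border_margin_um))

    for t in range(t0, t1 + 1):
        for det in frames[t]:
            key = det.key
            net.add_arc(
                net.pre[key], net.post[key], 1, detection_cost(det, z_thr),
                "observation", (key, key),
            )
            c_app = params.c_border
            if t == t0 or near_border(det):
                c_app *= 0.25
            c_dis = params.c_border
            if t == t1 or near_border(det):
                c_dis *= 0.25
            net.add_arc(net.DUMMY, net.pre[key], 1, c_app, "appear", (key,))
            net.add_arc(net.post[key], net.DUMMY, 1, c_dis, "disappear", (key,))

    trees = {
        t: cKDTree(np.array([d.centroid_um for d in frames[t]]))
        for t in range(t0, t1 + 1)
        if frames[t]
    }

    def offset(det: Detection, gap: int) -> np.ndarray:
        if flow_field is None:
            return np.zeros(3)
        return flow_field.query(det.centroid_um, det.frame) * gap

    # transition + skip arcs
    for t in range(t0, t1 + 1):
        if t not in trees:
            continue
        for gap in range(1, params.g_max + 1):
            t2 = t + gap
            if t2 > t1 or t2 not in trees:
                continue
            k = min(params.knn_transitions, len(frames[t2]))
            dist, nbr = trees[t2].query(
                np.array([d.centroid_um for d in frames[t]]), k=k
            )
            dist = np.asarray(dist).reshape(len(frames[t]), k)
            nbr = np.asarray(nbr).reshape(len(frames[t]), k)
            for i, a in enumerate(frames[t]):
                for j in range(k):
                    if not math.isfinite(dist[i, j]):
                        continue
                    b = frames[t2][nbr[i, j]]
                    cost = transition_cost(a, b, offset(a, gap), params, R)
                    net.add_arc(
                        net.post[a.key], net.pre[b.key], 1, cost,
                        "skip" if gap > 1 else "transition", (a.key, b.key),
                    )

    # division-child and merge-parent dummy arcs (adjacent frames only)
    for t in range(t0, t1):
        if t not in trees or (t + 1) not in trees:
            continue
        k = min(params.knn_div, len(frames[t + 1]))
        dist, nbr = trees[t + 1].query(
            np.array([d.centroid_um for d in frames[t]]), k=k
        )
        dist = np.asarray(dist).reshape(len(frames[t]), k)
        nbr = np.asarray(nbr).reshape(len(frames[t]), k)
        for i, parent in enumerate(frames[t]):
            for j in range(k):
                d = dist[i, j]
                if not math.isfinite(d) or d > R:
                    continue
                child = frames[t + 1][nbr[i, j]]
                c = (
                    params.div_discount * params.c_border
                    + d * d / (2.0 * params.sigma_motion_um**2)
                )
                net.add_arc(
                    net.DUMMY, net.pre[child.key], 1, c, "div_child",
                    (parent.key, child.key),
                )
        # symmetric: a detection at t may end by merging into a detection at t+1
        k2 = min(params.knn_div, len(frames[t]))
        dist2, nbr2 = trees[t].query(
            np.array([d.centroid_um for d in frames[t + 1]]), k=k2
        )
        dist2 = np.asarray(dist2).reshape(len(frames[t + 1]), k2)
        nbr2 = np.asarray(nbr2).reshape(len(frames[t + 1]), k2)
        for i, absorber in enumerate(frames[t + 1]):
            for j in range(k2):
                d = dist2[i, j]
                if not math.isfinite(d) or d > R:
                    continue
                ending = frames[t][nbr2[i, j]]
                c = (
                    params.div_discount * params.c_border
                    + d * d / (2.0 * params.sigma_motion_um**2)
                )
                net.add_arc(
                    net.post[ending.key], net.DUMMY, 1, c, "merge_parent",
                    (ending.key, absorber.key),
                )
    return net


# ---------------------------------------------------------------------------
# exact solving


def _solve_lp(net: CirculationNetwork) -> np.ndarray | None:
    m = len(net.arcs)
    rows, cols, vals = [], [], []
    for i, a in enumerate(net.arcs):
        rows.extend((a.tail, a.head))
        cols.extend((i, i))
        vals.extend((1.0, -1.0))
    A = sparse.coo_matrix((vals, (rows, cols)), shape=(net.n_nodes, m)).tocsr()
    c = np.array([a.cost for a in net.arcs], dtype=float)
    ub = np.array([a.cap for a in net.arcs], dtype=float)
    res = linprog(
        c,
        A_eq=A,
        b_eq=np.zeros(net.n_nodes),
        bounds=np.stack([np.zeros(m), ub], axis=1),
        method="highs",
    )
    if not res.success:
        return None
    x = res.x
    xr = np.round(x)
    if np.max(np.abs(x - xr)) > 1e-6:
        return None  # non-vertex solution; fall back to network simplex
    flow = xr.astype(np.int64)
    # conservation check after rounding
    imbalance = A @ flow
    if np.any(imbalance != 0):
        return None
    return flow


def _solve_network_simplex(net: CirculationNetwork) -> np.ndarray:
    import networkx as nx

    g = nx.MultiDiGraph()
    g.add_nodes_from(range(net.n_nodes), demand=0)
    for i, a in enumerate(net.arcs):
        g.add_edge(a.tail, a.head, key=i, capacity=a.cap, weight=a.cost)
    _, flow_dict = nx.network_simplex(g)
    flow = np.zeros(len(net.arcs), dtype=np.int64)
    for u, heads in flow_dict.items():
        for v, by_key in heads.items():
            for k, f in by_key.items():
                flow[k] = f
    return flow


def solve_circulation(net: CirculationNetwork) -> FlowSolution:
    """Exact integral minimum-cost circulation of the network.

    Every negative-cost cycle through detections is saturated at the
    optimum; the number of tracks emerges from the optimisation.  Empty
    networks yield zero flow at zero cost.
    """
    if not net.arcs:
        return FlowSolution(np.zeros(0, dtype=np.int64), 0, net)
    flow = _solve_lp(net)
    if flow is None:
        flow = _solve_network_simplex(net)
    cost = int(sum(int(f) * a.cost for f, a in zip(flow, net.arcs)))
    return FlowSolution(flow, cost, net)


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_association(
    dets: DetectionSet,
    params: LinkConfig,
    z_thr: float = 4.0,
    net: CirculationNetwork | None = None,
) -> int:
    """Exhaustive optimum over all feasible track decompositions.

    Independent of the LP/simplex path: a depth-first dynamic program over
    detections in (frame, id) order enumerating, for every detection,
    whether it is tracked and which successor (transition, skip) or exit
    (disappear, merge) and entry (appear, division-child) arcs carry its
    flow.  Uses the same arc set and integer costs as the solver.  Returns
    the optimal total cost (scaled integer).
    """
    if net is None:
        net = build_circulation(dets, params, z_thr)
    keys = sorted(net.pre.keys())
    n = len(keys)
    if n > 18:
        raise ValueError("instance too large for brute force")
    index = {k: i for i, k in enumerate(keys)}

    obs = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    entry = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    exit_ = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    succ: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for a in net.arcs:
        if a.kind == "observation":
            i = index[a.meta[0]]
            obs[i] = min(obs[i], a.cost)
        elif a.kind in ("appear", "div_child"):
            key = a.meta[0] if a.kind == "appear" else a.meta[1]
            i = index[key]
            entry[i] = min(entry[i], a.cost)
        elif a.kind in ("disappear", "merge_parent"):
            i = index[a.meta[0]]
            exit_[i] = min(exit_[i], a.cost)
        elif a.kind in ("transition", "skip"):
            i, j = index[a.meta[0]], index[a.meta[1]]
            succ[i].append((j, a.cost))
    for i in range(n):
        succ[i] = sorted(set(succ[i]))

    @lru_cache(maxsize=None)
    def best(i: int, claimed: int) -> int:
        if i == n:
            return 0
        options = []
        if claimed & (1 << i):
            base = obs[i]
            rest = claimed & ~(1 << i)
            options.append(base + exit_[i] + best(i + 1, rest))
            for j, c in succ[i]:
                if not claimed & (1 << j):
                    options.append(base + c + best(i + 1, rest | (1 << j)))
        else:
            options.append(best(i + 1, claimed))  # not tracked
            base = entry[i] + obs[i]
            options.append(base + exit_[i] + best(i + 1, claimed))
            for j, c in succ[i]:
                if not claimed & (1 << j):
                    options.append(base + c + best(i + 1, claimed | (1 << j)))
        return min(options)

    result = int(best(0, 0))
    best.cache_clear()
    return result


# ---------------------------------------------------------------------------
# tracklet extraction


def extract_tracklets(
    sol: FlowSolution, net: CirculationNetwork | None = None
) -> list[Tracklet]:
    """Decompose unit flows into tracklets.

    Division-child and merge-parent events stay on the tracklet as entry /
    exit annotations (``entry_kind``/``exit_kind`` + meta), not inlined as
    edges.  Every detection with positive observation flow appears in
    exactly one tracklet; frames skipped by a skip arc are recorded in
    ``gaps``.
    """
    net = net or sol.network
    succ: dict[tuple[int, int], tuple[int, int]] = {}
    entry: dict[tuple[int, int], tuple[str, tuple]] = {}
    exit_: dict[tuple[int, int], tuple[str, tuple]] = {}
    observed: set[tuple[int, int]] = set()
    for i, a in enumerate(net.arcs):
        if sol.flow[i] <= 0:
            continue
        if a.kind == "observation":
            observed.add(a.meta[0])
        elif a.kind in ("transition", "skip"):
            succ[a.meta[0]] = a.meta[1]
        elif a.kind in ("appear", "div_child"):
            key = a.meta[0] if a.kind == "appear" else a.meta[1]
            entry[key] = (a.kind, a.meta)
        elif a.kind in ("disappear", "merge_parent"):
            exit_[a.meta[0]] = (a.kind, a.meta)

    has_pred = set(succ.values())
    tracklets = []
    for key in sorted(observed):
        if key in has_pred:
            continue
        nodes = [key]
        while nodes[-1] in succ:
            nodes.append(succ[nodes[-1]])
        gaps = []
        for (ta, _), (tb, _) in zip(nodes, nodes[1:]):
            gaps.extend(range(ta + 1, tb))
        ek, em = entry.get(key, ("appear", (key,)))
        xk, xm = exit_.get(nodes[-1], ("disappear", (nodes[-1],)))
        tracklets.append(
            Tracklet(
                nodes=nodes,
                gaps=gaps,
                entry_kind=ek,
                exit_kind=xk,
                entry_meta=em,
                exit_meta=xm,
            )
        )
    return tracklets


def link_frames(
    dets: DetectionSet,
    config: PipelineConfig,
    strict: bool = False,
    flow_field=None,
    extent_um=None,
) -> tuple[CirculationNetwork, FlowSolution, list[Tracklet]]:
    """Convenience wrapper: build, solve and extract in one call.

    ``strict=True`` applies the conservative first-pass gate
    (``strict_factor x nominal radius``) used to produce high-confidence
    tracklets for the error-correction loop.
    """
    lp = config.link
    gate = None
    if strict:
        gate = lp.strict_factor * config.nominal_radius_um
    net = build_circulation(
        dets,
        lp,
        z_thr=config.detect.z_threshold,
        flow_field=flow_field,
        gating_radius_um=gate,
        border_margin_um=config.nominal_radius_um,
        extent_um=extent_um,
    )
    sol = solve_circulation(net)
    return net, sol, extract_tracklets(sol, net)
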