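"""Lineage forest: the pipeline's final product.

A forest of cell tracks with division edges, stored as a directed acyclic
graph.  Each node is one cell observation at one frame (or an interpolated
virtual node filling a closed gap); an edge points from a cell at frame t
to the same cell (or one of its daughters) at frame t+1.  Division nodes
have out-degree 2; no node has more than one parent.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import networkx as nx
import numpy as np


class LineageForest:
    """Directed forest of cell observations.

    Node attributes: ``frame`` (int), ``centroid`` (``(z, y, x)`` in µm),
    ``volume`` (µm³), ``interpolated`` (bool, True for virtual gap-filling
    nodes), and optionally ``det`` — the ``(frame, label)`` key of the
    detection the node came from.
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()
        self._next_id = 0

    # -- construction ------------------------------------------------------

    def add_node(
        self,
        frame: int,
        centroid,
        volume: float = 0.0,
        interpolated: bool = False,
        det=None,
        node_id: int | None = None,
    ) -> int:
        nid = self._next_id if node_id is None else int(node_id)
        if self.graph.has_node(nid):
            raise ValueError(f"node id {nid} already present")
        self.graph.add_node(
            nid,
            frame=int(frame),
            centroid=np.asarray(centroid, dtype=float),
            volume=float(volume),
            interpolated=bool(interpolated),
            det=det,
        )
        self._next_id = max(self._next_id, nid + 1)
        return nid

    def add_edge(self, parent: int, child: int) -> None:
        if self.graph.in_degree(child) >= 1:
            raise ValueError(f"node {child} already has a parent")
        if self.graph.out_degree(parent) >= 2:
            raise ValueError(f"node {parent} already has two children")
        self.graph.add_edge(parent, child)

    # -- queries -----------------------------------------------------------

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def nodes(self) -> Iterator[int]:
        return iter(self.graph.nodes)

    def frame_of(self, n: int) -> int:
        return self.graph.nodes[n]["frame"]

    def centroid_of(self, n: int) -> np.ndarray:
        return self.graph.nodes[n]["centroid"]

    def volume_of(self, n: int) -> float:
        return self.graph.nodes[n]["volume"]

    def parent(self, n: int) -> int | None:
        preds = list(self.graph.predecessors(n))
        return preds[0] if preds else None

    def children(self, n: int) -> list[int]:
        return sorted(self.graph.successors(n))

    def roots(self) -> list[int]:
        return sorted(n for n in self.graph.nodes if self.graph.in_degree(n) == 0)

    def leaves(self) -> list[int]:
        return sorted(n for n in self.graph.nodes if self.graph.out_degree(n) == 0)

    def division_nodes(self) -> list[int]:
        return sorted(n for n in self.graph.nodes if self.graph.out_degree(n) == 2)

    def nodes_at_frame(self, t: int) -> list[int]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["frame"] == t)

    def frames(self) -> list[int]:
        return sorted({d["frame"] for _, d in self.graph.nodes(data=True)})

    def edges(self) -> Iterable[tuple[int, int]]:
        return self.graph.edges

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        """Check the forest invariants; raise ``ValueError`` on violation."""
        g = self.graph
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("forest contains a cycle")
        for n in g.nodes:
            if g.in_degree(n) > 1:
                raise ValueError(f"node {n} has in-degree > 1")
            if g.out_degree(n) > 2:
                raise ValueError(f"node {n} has out-degree > 2")
        for u, v in g.edges:
            if g.nodes[v]["frame"] != g.nodes[u]["frame"] + 1:
                raise ValueError(
                    f"edge {u}->{v} spans frames "
                    f"{g.nodes[u]['frame']}->{g.nodes[v]['frame']}"
                )

    def tracks(self) -> list[list[int]]:
        """Maximal division-free segments (the CTC notion of a track).

        A segment starts at a root or at a daughter of a division and runs
        until a leaf or a division node (inclusive).
        """
        segs = []
        starts = list(self.roots())
        for d in self.division_nodes():
            starts.extend(self.children(d))
        for s in sorted(set(starts)):
            seg = [s]
            cur = s
            while True:
                ch = self.children(cur)
                if len(ch) != 1:
                    break
                cur = ch[0]
                seg.append(cur)
            segs.append(seg)
        return segs

    def root_to_leaf_paths(self) -> list[list[int]]:
        """Complete paths from every root to every reachable leaf."""
        paths = []
        for r in self.roots():
            stack = [[r]]
            while stack:
                p = stack.pop()
                ch = self.children(p[-1])
                if not ch:
                    paths.append(p)
                else:
                    for c in reversed(ch):
                        stack.append(p + [c])
        return sorted(paths)

    # -- comparison --------------------------------------------------------

    def canonical_form(self, decimals: int = 2):
        """Id-free representation: sorted node keys and edge keys.

        Node key = (frame, rounded centroid).  Used to compare forests that
        were built through different code paths (e.g. whole-scene vs
        batched processing) where integer node ids are meaningless.
        """
        key = {
            n: (d["frame"], tuple(np.round(d["centroid"], decimals)))
            for n, d in self.graph.nodes(data=True)
        }
        nodes = sorted(key.values())
        edges = sorted((key[u], key[v]) for u, v in self.graph.edges)
        return nodes, edges

    def topology_equal(self, other: "LineageForest", decimals: int = 2) -> bool:
        return self.canonical_form(decimals) == other.canonical_form(decimals)

    def copy(self) -> "LineageForest":
        out = LineageForest()
        out.graph = self.graph.copy()
        out._next_id = self._next_id
        return out
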