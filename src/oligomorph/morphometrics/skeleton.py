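"""Topological thinning and branch/junction graph extraction.

Branch length uses the chessboard-with-diagonals step convention: 1 per
orthogonal step, sqrt(2) per diagonal step, scaled by the pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize as sk_skeletonize

from oligomorph.segment import BinaryMask

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

DEFAULT_PRUNE_PX = 4.0


@dataclass
class SkeletonGraph:
    """Branches and junctions of a 1-px-wide skeleton.

    ``graph`` is a networkx MultiGraph whose nodes carry a representative
    pixel position (``pos``) and whose edges carry the pixel ``path`` and its
    ``length_px``.
    """

    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)
    pixel_size_um: float = 1.0

    @property
    def branch_lengths_px(self) -> np.ndarray:
        return np.array([d["length_px"] for _, _, d in self.graph.edges(data=True)])

    @property
    def branch_lengths_um(self) -> np.ndarray:
        return self.branch_lengths_px * self.pixel_size_um

    @property
    def total_length_um(self) -> float:
        return float(self.branch_lengths_um.sum()) if self.graph.number_of_edges() else 0.0

    @property
    def junction_nodes(self) -> list:
        return [n for n in self.graph.nodes if self.graph.degree(n) >= 3]

    @property
    def junction_count(self) -> int:
        return len(self.junction_nodes)

    @property
    def endpoint_nodes(self) -> list:
        return [n for n in self.graph.nodes if self.graph.degree(n) == 1]

    @property
    def n_branches(self) -> int:
        return self.graph.number_of_edges()


def _path_length(path: np.ndarray) -> float:
    if len(path) < 2:
        return 0.0
    steps = np.abs(np.diff(path, axis=0))
    return float(np.where(steps.sum(axis=1) == 2, np.sqrt(2.0), 1.0).sum())


def graph_from_skeleton(skel: np.ndarray, pixel_size_um: float = 1.0,
                        prune_px: float = DEFAULT_PRUNE_PX) -> SkeletonGraph:
    """Build the branch graph of a boolean skeleton image.

    Adjacent junction pixels are merged into a single node, so a rasterized Y
    counts one junction.  Spur branches shorter than ``prune_px`` are removed
    and pass-through nodes left behind are merged away.
    """
    skel = np.asarray(skel, dtype=bool)
    G = nx.MultiGraph()
    if not skel.any():
        return SkeletonGraph(G, pixel_size_um)

    # neighbor counts per skeleton pixel
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    ncount = ndi.convolve(skel.astype(int), kernel, mode="constant")
    ncount[~skel] = 0

    node_px = skel & ((ncount == 1) | (ncount >= 3))
    # isolated pixels and perfect cycles have no node pixels; give each
    # component without one a seed node so its branch is still traced
    comp_labels, n_comp = ndi.label(skel, structure=np.ones((3, 3)))
    for ci in range(1, n_comp + 1):
        comp = comp_labels == ci
        if not (node_px & comp).any():
            seed = tuple(np.argwhere(comp)[0])
            node_px[seed] = True

    # merge 8-adjacent node pixels into single graph nodes
    node_labels, n_nodes = ndi.label(node_px, structure=np.ones((3, 3)))
    reps: dict[int, tuple[int, int]] = {}
    for lbl in range(1, n_nodes + 1):
        px = np.argwhere(node_labels == lbl)
        reps[lbl] = tuple(px[px.shape[0] // 2])  # type: ignore[assignment]
        G.add_node(lbl, pos=reps[lbl])

    pix_node = node_labels  # 0 = chain pixel

    visited_steps: set[tuple[int, int, int, int]] = set()
    for lbl in range(1, n_nodes + 1):
        for start in map(tuple, np.argwhere(node_labels == lbl)):
            for dr, dc in _NEIGHBORS:
                r, c = start[0] + dr, start[1] + dc
                if not (0 <= r < skel.shape[0] and 0 <= c < skel.shape[1]):
                    continue
                if not skel[r, c]:
                    continue
                if (start[0], start[1], r, c) in visited_steps:
                    continue
                path = [start, (r, c)]
                visited_steps.add((start[0], start[1], r, c))
                visited_steps.add((r, c, start[0], start[1]))
                while pix_node[path[-1]] == 0:
                    cur = path[-1]
                    prev = path[-2]
                    nxt = None
                    for dr2, dc2 in _NEIGHBORS:
                        r2, c2 = cur[0] + dr2, cur[1] + dc2
                        if (r2, c2) == prev or not (
                            0 <= r2 < skel.shape[0] and 0 <= c2 < skel.shape[1]
                        ):
                            continue
                        if skel[r2, c2] and (cur[0], cur[1], r2, c2) not in visited_steps:
                            nxt = (r2, c2)
                            break
                    if nxt is None:
                        break
                    visited_steps.add((cur[0], cur[1], nxt[0], nxt[1]))
                    visited_steps.add((nxt[0], nxt[1], cur[0], cur[1]))
                    path.append(nxt)
                end_lbl = pix_node[path[-1]]
                if end_lbl == 0:
                    continue  # dead-ended inside a chain (visited); skip
                arr = np.array(path)
                if end_lbl == lbl and len(path) <= 3:
                    continue  # trivial self-steps within one node cluster
                G.add_edge(lbl, int(end_lbl), path=arr, length_px=_path_length(arr))

    _prune_spurs(G, prune_px)
    _merge_passthrough(G)
    return SkeletonGraph(G, pixel_size_um)


def _prune_spurs(G: nx.MultiGraph, prune_px: float) -> None:
    """Remove terminal branches shorter than ``prune_px`` (single pass)."""
    if prune_px <= 0:
        return
    to_drop = []
    for u, v, k, d in G.edges(keys=True, data=True):
        if d["length_px"] < prune_px and (G.degree(u) == 1 or G.degree(v) == 1) and u != v:
            if G.degree(u) == 1 and G.degree(v) == 1:
                continue  # whole component; keep
            to_drop.append((u, v, k))
    for u, v, k in to_drop:
        G.remove_edge(u, v, key=k)
    G.remove_nodes_from([n for n in list(G.nodes) if G.degree(n) == 0])


def _merge_passthrough(G: nx.MultiGraph) -> None:
    """Fuse nodes of degree 2 (ex-junctions after pruning) into one branch."""
    changed = True
    while changed:
        changed = False
        for n in list(G.nodes):
            if G.degree(n) != 2:
                continue
            edges = list(G.edges(n, keys=True, data=True))
            if len(edges) != 2:
                continue  # self-loop counts double; leave it
            (u1, v1, k1, d1), (u2, v2, k2, d2) = edges
            a = v1 if u1 == n else u1
            b = v2 if u2 == n else u2
            if a == n or b == n:
                continue  # self-loop
            p1 = d1["path"] if tuple(d1["path"][-1]) == G.nodes[n]["pos"] else d1["path"][::-1]
            p2 = d2["path"] if tuple(d2["path"][0]) == G.nodes[n]["pos"] else d2["path"][::-1]
            merged = np.vstack([p1, p2[1:]])
            G.remove_edge(u1, v1, key=k1)
            G.remove_edge(u2, v2, key=k2)
            G.remove_node(n)
            G.add_edge(a, b, path=merged, length_px=d1["length_px"] + d2["length_px"])
            changed = True
            break


def skeletonize_mask(mask: BinaryMask, prune_px: float = DEFAULT_PRUNE_PX) -> SkeletonGraph:
    """Thin the mask to 1-px centerlines and extract its branch graph."""
    skel = sk_skeletonize(mask.pixels)
    return graph_from_skeleton(skel, pixel_size_um=mask.pixel_size_um, prune_px=prune_px)
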