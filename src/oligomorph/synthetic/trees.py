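"""Random process trees: acyclic branch skeletons for synthetic cells.

A tree is a set of edges; each edge carries a polyline of (row, col) points.
Junctions are nodes of degree >= 3, so a plain Y (three arms from one point)
has exactly one junction and three branches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_STEP_PX = 2.0  # polyline sampling step


@dataclass
class TreeEdge:
    """One branch: polyline from parent node to tip/child node."""

    polyline: np.ndarray  # (k, 2) float (row, col)
    length_px: float
    parent_node: int
    child_node: int


@dataclass
class ProcessTree:
    """Acyclic skeleton rooted at the soma."""

    nodes: np.ndarray  # (m, 2) node coordinates, node 0 = soma
    edges: list[TreeEdge]

    @property
    def node_degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.nodes), dtype=int)
        for e in self.edges:
            deg[e.parent_node] += 1
            deg[e.child_node] += 1
        return deg

    @property
    def junction_count(self) -> int:
        return int(np.sum(self.node_degrees >= 3))

    @property
    def branch_lengths_px(self) -> np.ndarray:
        return np.array([e.length_px for e in self.edges], dtype=float)


def _wiggly_segment(
    rng: np.random.Generator,
    start: np.ndarray,
    angle: float,
    length: float,
    bend_sd: float,
    length_scale: float = 1.0,
) -> tuple[np.ndarray, float, float]:
    """March from ``start`` at ``angle`` with per-step angular jitter.

    ``length_scale`` stretches the realized segment without touching the
    random stream (step count is set by the unscaled length), so scenes with
    different scales but equal seeds share their geometry.  Returns the
    polyline, its arc length, and the exit angle.
    """
    n_steps = max(2, int(round(length / _STEP_PX)))
    step = length * length_scale / n_steps
    pts = [start.astype(float)]
    a = angle
    for _ in range(n_steps):
        a += rng.normal(0.0, bend_sd)
        pts.append(pts[-1] + step * np.array([np.sin(a), np.cos(a)]))
    poly = np.array(pts)
    arclen = float(np.sum(np.hypot(*np.diff(poly, axis=0).T)))
    return poly, arclen, a


def grow_tree(
    rng: np.random.Generator,
    soma: tuple[float, float],
    n_primary: int,
    segment_len_range: tuple[float, float],
    branch_prob: float,
    max_depth: int,
    bend_sd: float = 0.08,
    branch_angle: float = 0.55,
    length_scale: float = 1.0,
) -> ProcessTree:
    """Grow a random acyclic process tree rooted at ``soma``.

    ``n_primary`` arms leave the soma at roughly even angles; each segment may
    bifurcate with probability ``branch_prob`` until ``max_depth``.
    ``length_scale`` multiplies realized segment lengths while preserving the
    random stream (see :func:`_wiggly_segment`).
    """
    nodes = [np.asarray(soma, dtype=float)]
    edges: list[TreeEdge] = []
    if n_primary <= 0:
        return ProcessTree(np.array(nodes), edges)

    base = rng.uniform(0, 2 * np.pi)
    stack: list[tuple[int, float, int]] = []  # (node index, heading, depth)
    for i in range(n_primary):
        ang = base + 2 * np.pi * i / n_primary + rng.normal(0, 0.15)
        stack.append((0, ang, 1))

    while stack:
        parent, ang, depth = stack.pop()
        length = rng.uniform(*segment_len_range)
        poly, arclen, exit_ang = _wiggly_segment(rng, nodes[parent], ang, length,
                                                 bend_sd, length_scale)
        nodes.append(poly[-1])
        child = len(nodes) - 1
        edges.append(TreeEdge(poly, arclen, parent, child))
        if depth < max_depth and rng.random() < branch_prob:
            spread = branch_angle * rng.uniform(0.7, 1.3)
            stack.append((child, exit_ang - spread / 2, depth + 1))
            stack.append((child, exit_ang + spread / 2, depth + 1))
    return ProcessTree(np.array(nodes), edges)
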