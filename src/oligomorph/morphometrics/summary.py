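"""Per-field-of-view readouts: positivity, size, branch length, junctions."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from oligomorph.morphometrics.ridge import LineSet
from oligomorph.morphometrics.skeleton import SkeletonGraph
from oligomorph.segment import BinaryMask, Roi

log = logging.getLogger(__name__)


@dataclass
class MorphometricRecord:
    """One field of view's measurements plus its nesting metadata.

    Metrics that could not be computed are NaN and flagged in ``missing``.
    """

    group: str
    line_id: str
    fov_id: str
    marker: str
    method: str  # ridge | skeleton
    percent_positive: float = math.nan
    avg_cell_size: float = math.nan
    avg_branch_length: float = math.nan
    avg_junction_number: float = math.nan
    missing: bool = False


def percent_positive(marker_rois: list[Roi], dapi_rois: list[Roi]) -> float:
    """Percent of DAPI+ cells that are marker-positive.

    A marker ROI counts as one positive cell when it contains at least one
    DAPI ROI centroid.  Returns NaN (missing) when there are no DAPI ROIs.
    """
    if not dapi_rois:
        log.warning("percent_positive: no DAPI ROIs; recording missing value")
        return math.nan
    n_pos = 0
    centroids = [(int(round(r.centroid[0])), int(round(r.centroid[1]))) for r in dapi_rois]
    for roi in marker_rois:
        pix = {(int(r), int(c)) for r, c in roi.coords}
        if any(ctr in pix for ctr in centroids):
            n_pos += 1
    return min(100.0 * n_pos / len(dapi_rois), 100.0)


def average_cell_size(mask: BinaryMask, cell_count: int) -> float:
    """Total positive area divided by the cell number (um^2 per cell)."""
    if cell_count < 1:
        log.warning("average_cell_size: zero cells; recording missing value")
        return math.nan
    area_um2 = float(mask.pixels.sum()) * mask.pixel_size_um**2
    return area_um2 / cell_count


def cluster_point_count(points, radius: float) -> int:
    """Count clusters of points under single-linkage at ``radius``-px reach.

    Rasterized junctions of one true branching point can split into several
    nearby graph nodes; counting clusters undoes that.
    """
    pts = [np.asarray(p, dtype=float) for p in points]
    if not pts:
        return 0
    if radius <= 0:
        return len(pts)
    n = len(pts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(pts[i] - pts[j])) <= radius:
                parent[find(j)] = find(i)
    return len({find(i) for i in range(n)})


def summarize_morphology(lines_or_graph: LineSet | SkeletonGraph,
                         cell_count: int, method: str,
                         junction_merge_px: float = 6.0) -> tuple[float, float]:
    """(average branch length in um, junctions per cell) for one field.

    Branch averaging is per branch within the field; junction number is
    normalized by the cell count, with junction points closer than
    ``junction_merge_px`` counted once.  Both are NaN when nothing was
    detected or ``cell_count`` is zero.
    """
    if method not in ("ridge", "skeleton"):
        raise ValueError(f"unknown method {method!r}")
    if cell_count < 1:
        return math.nan, math.nan
    if isinstance(lines_or_graph, LineSet):
        lengths = lines_or_graph.lengths_um
        junctions = list(lines_or_graph.junction_points)
    else:
        lengths = lines_or_graph.branch_lengths_um
        junctions = [lines_or_graph.graph.nodes[n]["pos"]
                     for n in lines_or_graph.junction_nodes]
    if lengths.size == 0:
        return math.nan, math.nan
    n_junctions = cluster_point_count(junctions, junction_merge_px)
    return float(lengths.mean()), n_junctions / cell_count
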