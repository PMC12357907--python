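"""Sub-pixel curvilinear structure detection via Hessian eigenanalysis.

Line points are pixels where the second directional derivative across the
line (the most negative Hessian eigenvalue of the Gaussian-smoothed image)
is strong and the intensity maximum along the eigendirection falls inside
the pixel; the sub-pixel offset comes from the first-order Taylor step.
Detected points are linked into polylines with hysteresis (strong response
starts a line, weak response extends it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize as sk_skeletonize

from oligomorph.image import ChannelImage
from oligomorph.morphometrics.skeleton import graph_from_skeleton, DEFAULT_PRUNE_PX

_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass
class LineSet:
    """Polylines with per-point sub-pixel coordinates and widths."""

    polylines: list[np.ndarray] = field(default_factory=list)  # (k, 2) float
    widths: list[np.ndarray] = field(default_factory=list)  # (k,) per-point width
    junction_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    pixel_size_um: float = 1.0

    @property
    def lengths_px(self) -> np.ndarray:
        out = []
        for poly in self.polylines:
            out.append(float(np.sum(np.hypot(*np.diff(poly, axis=0).T))))
        return np.array(out)

    @property
    def lengths_um(self) -> np.ndarray:
        return self.lengths_px * self.pixel_size_um

    @property
    def total_length_um(self) -> float:
        return float(self.lengths_um.sum()) if self.polylines else 0.0

    @property
    def junction_count(self) -> int:
        return len(self.junction_points)


def _hessian_line_points(px: np.ndarray, sigma: float):
    """Response, normal direction and sub-pixel offset for every pixel."""
    I = px.astype(float)
    Ir = ndi.gaussian_filter(I, sigma, order=(1, 0))
    Ic = ndi.gaussian_filter(I, sigma, order=(0, 1))
    Irr = ndi.gaussian_filter(I, sigma, order=(2, 0))
    Icc = ndi.gaussian_filter(I, sigma, order=(0, 2))
    Irc = ndi.gaussian_filter(I, sigma, order=(1, 1))

    half_diff = (Irr - Icc) / 2.0
    root = np.sqrt(half_diff**2 + Irc**2)
    ev = (Irr + Icc) / 2.0 - root  # most negative eigenvalue: bright ridges

    # eigenvector (normal to the line) for ev; pick the better-conditioned form
    nr1, nc1 = Irc, ev - Irr
    nr2, nc2 = ev - Icc, Irc
    use2 = (nr1**2 + nc1**2) < (nr2**2 + nc2**2)
    nr = np.where(use2, nr2, nr1)
    nc = np.where(use2, nc2, nc1)
    norm = np.hypot(nr, nc)
    norm[norm == 0] = 1.0
    nr, nc = nr / norm, nc / norm

    # sub-pixel maximum along the normal: t* = -(grad . n) / (n^T H n)
    denom = ev.copy()
    denom[denom == 0] = -1e-12
    t = -(Ir * nr + Ic * nc) / denom

    response = np.clip(-ev, 0, None) * sigma**2
    on_line = (np.abs(t * nr) <= 0.6) & (np.abs(t * nc) <= 0.6)
    return response, nr, nc, t, on_line


def detect_ridges(image: ChannelImage, sigma: float = 1.5,
                  low_contrast: float = 1.5, high_contrast: float = 4.0,
                  prune_px: float = DEFAULT_PRUNE_PX) -> LineSet:
    """Extract sub-pixel centerlines of bright curvilinear structures.

    ``sigma`` should be at least line width / sqrt(3).  ``high_contrast``
    starts lines, ``low_contrast`` extends them (hysteresis on the
    scale-normalized second-derivative response).  A blank image yields an
    empty :class:`LineSet`.
    """
    if not (0 <= low_contrast < high_contrast):
        raise ValueError("need 0 <= low_contrast < high_contrast")
    px = np.asarray(image.pixels, dtype=float)
    response, nr, nc, t, on_line = _hessian_line_points(px, sigma)

    weak = on_line & (response >= low_contrast)
    strong = on_line & (response >= high_contrast)
    if not strong.any():
        return LineSet(pixel_size_um=image.pixel_size_um)

    labels, _ = ndi.label(weak, structure=_SQUARE3)
    keep_labels = np.unique(labels[strong])
    keep_labels = keep_labels[keep_labels > 0]
    kept = np.isin(labels, keep_labels)

    # bridge 1-px gaps (e.g. at crossings where the ridge model fails), thin
    kept = ndi.binary_closing(kept, structure=_SQUARE3)
    skel = sk_skeletonize(kept)

    sg = graph_from_skeleton(skel, pixel_size_um=image.pixel_size_um, prune_px=prune_px)

    # map pixel paths to sub-pixel positions where offsets are valid
    offs_r = np.where(on_line, t * nr, 0.0)
    offs_c = np.where(on_line, t * nc, 0.0)
    polylines, widths = [], []
    for _, _, d in sg.graph.edges(data=True):
        path = d["path"]
        sub = path.astype(float).copy()
        sub[:, 0] += offs_r[path[:, 0], path[:, 1]]
        sub[:, 1] += offs_c[path[:, 0], path[:, 1]]
        if len(sub) < 2:
            continue
        polylines.append(sub)
        widths.append(np.full(len(sub), 2.0 * sigma))

    junctions = [np.asarray(sg.graph.nodes[n]["pos"], dtype=float) for n in sg.junction_nodes]
    junctions += _endpoint_cluster_junctions(polylines, exclude=junctions)
    jarr = np.array(junctions) if junctions else np.empty((0, 2))
    return LineSet(polylines=polylines, widths=widths, junction_points=jarr,
                   pixel_size_um=image.pixel_size_um)


def _endpoint_cluster_junctions(polylines: list[np.ndarray],
                                exclude: list[np.ndarray],
                                radius: float = 3.0) -> list[np.ndarray]:
    """Clusters of >= 3 polyline end points count as junctions.

    Clusters within ``radius`` of an already-known junction are dropped.
    """
    ends = [p[0] for p in polylines] + [p[-1] for p in polylines]
    if len(ends) < 3:
        return []
    ends_arr = np.array(ends)
    used = np.zeros(len(ends), dtype=bool)
    found = []
    for i in range(len(ends)):
        if used[i]:
            continue
        d = np.hypot(*(ends_arr - ends_arr[i]).T)
        members = np.where((d <= radius) & ~used)[0]
        if len(members) >= 3:
            ctr = ends_arr[members].mean(axis=0)
            if all(np.hypot(*(ctr - np.asarray(x))) > radius for x in exclude):
                found.append(ctr)
            used[members] = True
    return found
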