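"""Thresholding, binary cleanup and ROI filtering.

The two threshold variants minimize Huang's measure of fuzziness over the
256-bin histogram: ``huang`` scans every candidate exhaustively, ``huang2``
runs a coarse-to-fine search over the same objective.  ROI filters implement
the bleed-through correction: branched cells are kept by a solidity cut-off
and nucleus-shaped artifacts are dropped by their overlap with DAPI ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed as sk_watershed

from oligomorph.image import ChannelImage

_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass
class BinaryMask:
    pixels: np.ndarray  # 2-D bool
    source_channel: str = "DAPI"
    threshold_used: float | None = None
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class Roi:
    """A labelled 8-connected pixel region with shape features."""

    label: int
    coords: np.ndarray  # (n, 2) 0-based (row, col)
    image_shape: tuple[int, int]
    area_px: int
    centroid: tuple[float, float]
    solidity: float
    bbox: tuple[int, int, int, int]
    pixel_size_um: float = 1.0
    flags: dict = field(default_factory=dict)

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um**2

    def mask(self) -> np.ndarray:
        m = np.zeros(self.image_shape, dtype=bool)
        m[self.coords[:, 0], self.coords[:, 1]] = True
        return m


# ---------------------------------------------------------------------------
# Huang fuzzy-entropy thresholding
# ---------------------------------------------------------------------------

def huang_objective(hist: np.ndarray) -> np.ndarray:
    """Fuzziness E(t) for every candidate threshold t = 0..254.

    Membership of grey level g is 1 / (1 + |g - mu| / C) with mu the mean of
    the side of the threshold g falls on and C the grey-level span; E(t) is
    the histogram-weighted Shannon entropy of the memberships.  Thresholds
    with an empty side get infinite fuzziness.
    """
    hist = np.asarray(hist, dtype=float)
    if hist.size != 256:
        raise ValueError("expected a 256-bin histogram")
    g = np.arange(256, dtype=float)
    nz = np.nonzero(hist)[0]
    if nz.size == 0:
        raise ValueError("empty histogram")
    first, last = int(nz[0]), int(nz[-1])
    span = max(last - first, 1)

    w = np.cumsum(hist)
    wg = np.cumsum(hist * g)
    total_w, total_wg = w[-1], wg[-1]

    E = np.full(255, np.inf)
    for t in range(first, last):
        w0, w1 = w[t], total_w - w[t]
        if w0 <= 0 or w1 <= 0:
            continue
        mu0 = wg[t] / w0
        mu1 = (total_wg - wg[t]) / w1
        mu = np.where(g <= t, mu0, mu1)
        u = 1.0 / (1.0 + np.abs(g - mu) / span)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = -u * np.log(u) - (1 - u) * np.log1p(-u)
        s[~np.isfinite(s)] = 0.0
        E[t] = float(np.dot(hist, s))
    return E


def _huang_exhaustive(hist: np.ndarray) -> int:
    E = huang_objective(hist)
    return int(np.argmin(E))  # argmin takes the lowest index on ties


def _huang_coarse_to_fine(hist: np.ndarray, coarse_step: int = 8, n_refine: int = 6) -> int:
    """Bounded coarse-to-fine minimization of the same fuzziness objective.

    The fine pass searches +-coarse_step around the ``n_refine`` best coarse
    candidates, which protects against narrow basins between grid points.
    """
    E = huang_objective(hist)
    candidates = np.arange(0, 255, coarse_step)
    order = list(np.argsort(E[candidates], kind="stable")[:n_refine])
    # the objective plateaus across empty histogram gaps: also refine around
    # every coarse candidate numerically tied with the coarse minimum
    e_min = np.min(E[candidates])
    ties = np.nonzero(E[candidates] <= e_min + 1e-9 * max(abs(e_min), 1.0))[0]
    refine = sorted(set(order) | set(ties.tolist()))
    best_t, best_e = 0, np.inf
    for ci in refine:
        c = candidates[ci]
        half = 2 * coarse_step  # widened: dips can hide just beyond the grid spacing
        window = np.arange(max(c - half, 0), min(c + half, 254) + 1)
        t = window[int(np.argmin(E[window]))]
        e = E[t]
        if e < best_e - 1e-15 or (abs(e - best_e) <= 1e-15 and t < best_t):
            best_t, best_e = int(t), float(e)
    return best_t


def huang_threshold(image: ChannelImage, variant: str = "huang") -> tuple[int, BinaryMask]:
    """Threshold by minimal fuzziness; mask = pixels strictly above it.

    ``variant='huang'`` scans all 255 candidates; ``'huang2'`` refines a
    coarse grid.  Both agree exactly on well-separated bimodal histograms.
    """
    if variant not in ("huang", "huang2"):
        raise ValueError(f"unknown variant {variant!r}")
    px = np.asarray(image.pixels)
    if px.min() == px.max():
        raise ValueError("degenerate histogram: image has a single grey level")
    hist = np.bincount(np.clip(px, 0, 255).astype(np.int64).ravel(), minlength=256)[:256]
    t = _huang_exhaustive(hist) if variant == "huang" else _huang_coarse_to_fine(hist)
    mask = BinaryMask(px > t, source_channel=image.channel, threshold_used=t,
                      pixel_size_um=image.pixel_size_um)
    return t, mask


# ---------------------------------------------------------------------------
# binary operations
# ---------------------------------------------------------------------------

def _watershed_split(mask: np.ndarray) -> np.ndarray:
    """Split touching blobs along distance-transform watershed lines."""
    if not mask.any():
        return mask
    dist = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(dist, min_distance=4, labels=mask, exclude_border=False)
    if len(peaks) == 0:
        return mask
    markers = np.zeros(mask.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    markers, _ = ndi.label(ndi.binary_dilation(markers > 0, _SQUARE3))
    labels = sk_watershed(-dist, markers=markers, mask=mask, watershed_line=True)
    return mask & (labels > 0)


_BINARY_OPS = {
    "erode": lambda m: ndi.binary_erosion(m, structure=_SQUARE3),
    "dilate": lambda m: ndi.binary_dilation(m, structure=_SQUARE3),
    "open": lambda m: ndi.binary_opening(m, structure=_SQUARE3),
    "close": lambda m: ndi.binary_closing(m, structure=_SQUARE3),
    "watershed": _watershed_split,
}


def apply_binary_ops(mask: BinaryMask, ops: list[str]) -> BinaryMask:
    """Apply morphological cleanup steps in order (3x3 element, 1 iteration)."""
    if not ops:
        raise ValueError("ops must be non-empty")
    out = mask.pixels
    for op in ops:
        if op not in _BINARY_OPS:
            raise ValueError(f"unknown binary op {op!r}; choose from {sorted(_BINARY_OPS)}")
        out = _BINARY_OPS[op](out)
    return BinaryMask(out, source_channel=mask.source_channel,
                      threshold_used=mask.threshold_used,
                      pixel_size_um=mask.pixel_size_um)


# ---------------------------------------------------------------------------
# ROI extraction and filters
# ---------------------------------------------------------------------------

def extract_rois(mask: BinaryMask, min_area_px: int = 20) -> list[Roi]:
    """8-connected components of area >= ``min_area_px`` with shape features."""
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    labels = cc_label(mask.pixels, connectivity=2)
    rois: list[Roi] = []
    for rp in regionprops(labels):
        if rp.area < min_area_px:
            continue
        rois.append(Roi(
            label=int(rp.label),
            coords=rp.coords,
            image_shape=mask.shape,
            area_px=int(rp.area),
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            solidity=float(rp.solidity),
            bbox=tuple(int(v) for v in rp.bbox),  # type: ignore[arg-type]
            pixel_size_um=mask.pixel_size_um,
        ))
    return rois


def filter_by_solidity(rois: list[Roi], max_solidity: float = 0.7) -> list[Roi]:
    """Keep ROIs with solidity strictly below the cut-off (order preserved)."""
    kept = []
    for roi in rois:
        ok = roi.solidity < max_solidity
        roi.flags["kept_solidity"] = bool(ok)
        if ok:
            kept.append(roi)
    return kept


def filter_bleedthrough(target_rois: list[Roi], reference_rois: list[Roi],
                        max_overlap: float = 0.6) -> list[Roi]:
    """Keep target ROIs whose overlap with the reference union is < cut-off.

    Overlap is the fraction of the *target* ROI's pixels lying inside the
    union of reference ROIs.
    """
    if target_rois and reference_rois:
        if target_rois[0].image_shape != reference_rois[0].image_shape:
            raise ValueError("target and reference ROIs come from different image shapes")
    if not target_rois:
        return []
    shape = target_rois[0].image_shape
    ref_union = np.zeros(shape, dtype=bool)
    for roi in reference_rois:
        ref_union[roi.coords[:, 0], roi.coords[:, 1]] = True
    kept = []
    for roi in target_rois:
        shared = int(ref_union[roi.coords[:, 0], roi.coords[:, 1]].sum())
        overlap = shared / roi.area_px
        ok = overlap < max_overlap
        roi.flags["overlap_fraction"] = overlap
        roi.flags["kept_overlap"] = bool(ok)
        if ok:
            kept.append(roi)
    return kept


def rois_to_dataframe(rois: list[Roi]):
    """ROI feature table (one row per ROI) for CSV export."""
    import pandas as pd

    return pd.DataFrame([
        {
            "label": r.label,
            "area_px": r.area_px,
            "area_um2": r.area_um2,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
            "solidity": r.solidity,
            "kept_solidity": r.flags.get("kept_solidity"),
            "kept_overlap": r.flags.get("kept_overlap"),
        }
        for r in rois
    ])


def rois_to_mask(rois: list[Roi], shape: tuple[int, int]) -> BinaryMask:
    """Union of ROI pixel sets as a mask (used to feed morphometrics)."""
    m = np.zeros(shape, dtype=bool)
    for roi in rois:
        m[roi.coords[:, 0], roi.coords[:, 1]] = True
    px = rois[0].pixel_size_um if rois else 1.0
    return BinaryMask(m, pixel_size_um=px)
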