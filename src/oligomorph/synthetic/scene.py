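"""Scene generation and rendering with exact ground truth.

A :class:`GroundTruthScene` records nuclei and cells (with their process
skeletons) in continuous coordinates; :func:`render_channels` rasterizes it
into a DAPI channel and a marker channel with bleed-through, vignetting and
shot/read noise.  Rendering never mutates the truth records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from oligomorph.image import ChannelImage
from oligomorph.synthetic.trees import ProcessTree, TreeEdge, grow_tree


@dataclass
class SceneParams:
    """Knobs for :func:`generate_scene`.

    Marker-dependent morphology: O4 cells are compact (large soma, few short
    processes); MBP cells carry branched trees.  ``tree_*`` fields override
    the marker defaults when set.
    """

    image_shape: tuple[int, int] = (256, 256)
    n_nuclei: int = 10
    n_cells: int = 6
    marker: str = "MBP"
    colocalized_fraction: float = 1.0
    pixel_size_um: float = 1.0
    bit_depth: int = 8

    nucleus_radius_range: tuple[float, float] = (4.5, 7.0)
    nucleus_intensity_range: tuple[float, float] = (120.0, 200.0)
    soma_radius_range: tuple[float, float] = (3.0, 5.0)
    cell_intensity_range: tuple[float, float] = (120.0, 190.0)
    process_width_px: float = 3.0

    # tree morphology; None -> marker default
    tree_n_primary: tuple[int, int] | None = None
    tree_segment_len: tuple[float, float] | None = None
    tree_branch_prob: float | None = None
    tree_max_depth: int | None = None

    bleed_coefficient: float = 0.0
    bleed_blur_px: float = 2.0
    illumination_amplitude: float = 0.0
    photon_scale: float = float("inf")  # photons per grey level; inf = no shot noise
    read_sd: float = 0.0

    # length scaling applied to every tree segment; used to inject group
    # effects on branch length into rendered images
    length_scale: float = 1.0

    def tree_spec(self) -> dict:
        if self.marker == "MBP":
            spec = dict(n_primary=(3, 5), segment_len=(18.0, 32.0), branch_prob=0.45, max_depth=3)
        else:  # O4: compact with short stubby processes
            spec = dict(n_primary=(2, 4), segment_len=(6.0, 12.0), branch_prob=0.1, max_depth=2)
        if self.tree_n_primary is not None:
            spec["n_primary"] = self.tree_n_primary
        if self.tree_segment_len is not None:
            spec["segment_len"] = self.tree_segment_len
        if self.tree_branch_prob is not None:
            spec["branch_prob"] = self.tree_branch_prob
        if self.tree_max_depth is not None:
            spec["max_depth"] = self.tree_max_depth
        return spec


@dataclass
class CellTruth:
    """Ground truth for one cell."""

    soma_center: tuple[float, float]
    soma_radius: float
    intensity: float
    marker: str
    tree: ProcessTree
    process_width_px: float
    colocalized_nucleus: int | None

    @property
    def branch_lengths_px(self) -> np.ndarray:
        return self.tree.branch_lengths_px

    @property
    def junction_count(self) -> int:
        return self.tree.junction_count


@dataclass
class GroundTruthScene:
    """Everything needed to render the channels and to verify any measurement."""

    image_shape: tuple[int, int]
    nuclei: list[dict]  # center, semi_axes, angle, intensity
    cells: list[CellTruth]
    bleed_coefficient: float
    bleed_blur_px: float
    illumination_field: np.ndarray
    photon_scale: float
    read_sd: float
    pixel_size_um: float
    bit_depth: int
    marker: str
    seed: int
    params: SceneParams = field(repr=False, default=None)  # type: ignore[assignment]

    # ---- exact truth accessors -------------------------------------------
    def true_branch_lengths_um(self) -> np.ndarray:
        if not self.cells:
            return np.array([])
        lens = [c.branch_lengths_px for c in self.cells]
        return np.concatenate(lens) * self.pixel_size_um if lens else np.array([])

    def true_mean_branch_length_um(self) -> float:
        lens = self.true_branch_lengths_um()
        return float(lens.mean()) if lens.size else float("nan")

    def true_junction_count(self) -> int:
        return int(sum(c.junction_count for c in self.cells))

    def true_junctions_per_cell(self) -> float:
        return self.true_junction_count() / len(self.cells) if self.cells else float("nan")

    def true_percent_positive(self) -> float:
        if not self.nuclei:
            return float("nan")
        n_pos = sum(1 for c in self.cells if c.colocalized_nucleus is not None)
        return 100.0 * n_pos / len(self.nuclei)


def _poisson_disk(rng: np.random.Generator, n: int, shape: tuple[int, int],
                  margin: float, min_dist: float, max_tries: int = 2000) -> np.ndarray:
    """Rejection-sample ``n`` points at pairwise distance >= min_dist."""
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n and tries < max_tries:
        tries += 1
        p = np.array([
            rng.uniform(margin, shape[0] - margin),
            rng.uniform(margin, shape[1] - margin),
        ])
        if all(np.hypot(*(p - q)) >= min_dist for q in pts):
            pts.append(p)
    while len(pts) < n:  # give up on spacing rather than fail
        pts.append(np.array([
            rng.uniform(margin, shape[0] - margin),
            rng.uniform(margin, shape[1] - margin),
        ]))
    return np.array(pts) if pts else np.empty((0, 2))


def _illumination_field(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    """Low-order polynomial vignetting gain, mean ~1, strictly positive."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    r = (rr - shape[0] / 2) / (shape[0] / 2)
    c = (cc - shape[1] / 2) / (shape[1] / 2)
    gain = 1.0 + amplitude * (0.5 - (r**2 + c**2) / 2.0)
    return np.clip(gain, 0.05, None)


def generate_scene(params: SceneParams, seed: int) -> GroundTruthScene:
    """Deterministically generate a ground-truthed scene.

    Raises
    ------
    ValueError
        On non-positive image dimensions or negative counts.
    """
    rows, cols = params.image_shape
    if rows < 64 or cols < 64:
        raise ValueError("image_shape must be at least 64x64")
    if params.n_nuclei < 0 or params.n_cells < 0:
        raise ValueError("counts must be >= 0")
    if params.bleed_coefficient < 0:
        raise ValueError("bleed_coefficient must be >= 0")

    rng = np.random.default_rng([seed, 0xA11CE])
    margin = max(params.nucleus_radius_range[1], 10.0)
    # spacing keeps cells resolvable so that morphometrics are attributable
    min_dist = min(rows, cols) / max(2.0, np.sqrt(max(params.n_cells, params.n_nuclei, 1)) + 1)
    centers = _poisson_disk(rng, params.n_nuclei, (rows, cols), margin, min_dist)

    nuclei = []
    for ctr in centers:
        a = rng.uniform(*params.nucleus_radius_range)
        b = a * rng.uniform(0.75, 1.0)
        nuclei.append({
            "center": (float(ctr[0]), float(ctr[1])),
            "semi_axes": (float(a), float(b)),
            "angle": float(rng.uniform(0, np.pi)),
            "intensity": float(rng.uniform(*params.nucleus_intensity_range)),
        })

    n_coloc = int(round(params.colocalized_fraction * params.n_cells))
    n_coloc = min(n_coloc, len(nuclei))
    spec = params.tree_spec()

    cells: list[CellTruth] = []
    free_centers = _poisson_disk(
        rng, params.n_cells - n_coloc, (rows, cols), margin, min_dist
    ) if params.n_cells > n_coloc else np.empty((0, 2))
    for i in range(params.n_cells):
        if i < n_coloc:
            nuc_idx: int | None = i
            soma = np.asarray(nuclei[i]["center"]) + rng.normal(0, 1.0, size=2)
        else:
            nuc_idx = None
            soma = free_centers[i - n_coloc]
        lo, hi = spec["n_primary"]
        n_primary = int(rng.integers(lo, hi + 1))
        tree = grow_tree(
            rng,
            (float(soma[0]), float(soma[1])),
            n_primary=n_primary,
            segment_len_range=spec["segment_len"],
            branch_prob=spec["branch_prob"],
            max_depth=spec["max_depth"],
            length_scale=params.length_scale,
        )
        tree = _clip_tree(tree, (rows, cols), pad=3.0)
        cells.append(CellTruth(
            soma_center=(float(soma[0]), float(soma[1])),
            soma_radius=float(rng.uniform(*params.soma_radius_range)),
            intensity=float(rng.uniform(*params.cell_intensity_range)),
            marker=params.marker,
            tree=tree,
            process_width_px=params.process_width_px,
            colocalized_nucleus=nuc_idx,
        ))

    return GroundTruthScene(
        image_shape=(rows, cols),
        nuclei=nuclei,
        cells=cells,
        bleed_coefficient=params.bleed_coefficient,
        bleed_blur_px=params.bleed_blur_px,
        illumination_field=_illumination_field((rows, cols), params.illumination_amplitude),
        photon_scale=params.photon_scale,
        read_sd=params.read_sd,
        pixel_size_um=params.pixel_size_um,
        bit_depth=params.bit_depth,
        marker=params.marker,
        seed=seed,
        params=params,
    )


def _clip_tree(tree: ProcessTree, shape: tuple[int, int], pad: float) -> ProcessTree:
    """Truncate edges at the image border so every mask stays in bounds."""
    hi = np.array([shape[0] - 1 - pad, shape[1] - 1 - pad])
    lo = np.array([pad, pad])
    new_edges = []
    for e in tree.edges:
        inside = np.all((e.polyline >= lo) & (e.polyline <= hi), axis=1)
        if not inside[0]:
            continue  # parent node out of bounds; drop branch
        if inside.all():
            new_edges.append(e)
            continue
        k = int(np.argmin(inside))  # first outside point
        if k < 2:
            continue
        poly = e.polyline[:k]
        arclen = float(np.sum(np.hypot(*np.diff(poly, axis=0).T)))
        new_edges.append(TreeEdge(poly, arclen, e.parent_node, e.child_node))
    return ProcessTree(tree.nodes, new_edges)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _draw_polyline(canvas: np.ndarray, poly: np.ndarray, value: float) -> None:
    """Deposit ``value`` along a densely sampled polyline (nearest pixel)."""
    seg = np.diff(poly, axis=0)
    seglen = np.hypot(*seg.T)
    total = seglen.sum()
    if total <= 0:
        return
    n = max(int(np.ceil(total * 2)), 2)  # ~0.5 px sampling
    t = np.linspace(0, 1, n)
    cum = np.concatenate([[0], np.cumsum(seglen)]) / total
    rr = np.interp(t, cum, poly[:, 0])
    cc = np.interp(t, cum, poly[:, 1])
    ri = np.clip(np.round(rr).astype(int), 0, canvas.shape[0] - 1)
    ci = np.clip(np.round(cc).astype(int), 0, canvas.shape[1] - 1)
    # keep one deposit per pixel so ridge amplitude is independent of sampling
    idx = np.unique(ri * canvas.shape[1] + ci)
    canvas.ravel()[idx] = np.maximum(canvas.ravel()[idx], value)


def _render_nuclei(scene: GroundTruthScene) -> np.ndarray:
    rows, cols = scene.image_shape
    img = np.zeros((rows, cols))
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    for nuc in scene.nuclei:
        r0, c0 = nuc["center"]
        a, b = nuc["semi_axes"]
        th = nuc["angle"]
        dr, dc = rr - r0, cc - c0
        u = dr * np.cos(th) + dc * np.sin(th)
        v = -dr * np.sin(th) + dc * np.cos(th)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        img[inside] = np.maximum(img[inside], nuc["intensity"])
    return ndi.gaussian_filter(img, 1.0)


def _render_marker(scene: GroundTruthScene) -> np.ndarray:
    rows, cols = scene.image_shape
    img = np.zeros((rows, cols))
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    for cell in scene.cells:
        # Gaussian-profile ridges: impulse polyline blurred to the target width
        ridge = np.zeros((rows, cols))
        for e in cell.tree.edges:
            _draw_polyline(ridge, e.polyline, 1.0)
        sigma = max(cell.process_width_px / 2.355, 0.6)  # FWHM = process width
        if ridge.any():
            ridge = ndi.gaussian_filter(ridge, sigma)
            peak = ridge.max()
            if peak > 0:
                img += ridge * (cell.intensity / peak)
        # soma blob
        r0, c0 = cell.soma_center
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        img += cell.intensity * np.exp(-d2 / (2 * cell.soma_radius**2))
    return img


def _apply_noise(signal: np.ndarray, scene: GroundTruthScene, sub_seed: int) -> np.ndarray:
    rng = np.random.default_rng([scene.seed, 0x5EED, sub_seed])
    out = signal
    if np.isfinite(scene.photon_scale):
        out = rng.poisson(np.clip(out, 0, None) * scene.photon_scale) / scene.photon_scale
    if scene.read_sd > 0:
        out = out + rng.normal(0.0, scene.read_sd, size=out.shape)
    return out


def render_channels(scene: GroundTruthScene) -> tuple[ChannelImage, ChannelImage]:
    """Rasterize the scene into (DAPI, marker) channel images.

    The marker channel is ``illumination * (marker + bleed * blur(DAPI)) + noise``;
    the DAPI channel carries no marker signal.  Output is quantized to the
    scene's bit depth.
    """
    dapi_sig = _render_nuclei(scene)
    marker_sig = _render_marker(scene)
    if scene.bleed_coefficient > 0:
        bleed = scene.bleed_coefficient * ndi.gaussian_filter(dapi_sig, scene.bleed_blur_px)
    else:
        bleed = 0.0
    gain = scene.illumination_field
    dapi_px = _apply_noise(gain * dapi_sig, scene, sub_seed=0)
    marker_px = _apply_noise(gain * (marker_sig + bleed), scene, sub_seed=1)

    max_val = 2**scene.bit_depth - 1
    dtype = np.uint8 if scene.bit_depth <= 8 else np.uint16
    dapi_q = np.clip(np.round(dapi_px), 0, max_val).astype(dtype)
    marker_q = np.clip(np.round(marker_px), 0, max_val).astype(dtype)

    dapi = ChannelImage(dapi_q, channel="DAPI", pixel_size_um=scene.pixel_size_um,
                        bit_depth=scene.bit_depth, provenance=["render"])
    marker = ChannelImage(marker_q, channel=scene.marker,
                          pixel_size_um=scene.pixel_size_um,
                          bit_depth=scene.bit_depth, provenance=["render"])
    return dapi, marker


# ---------------------------------------------------------------------------
# persistence: multi-page TIFF + JSON truth sidecar
# ---------------------------------------------------------------------------

def save_scene(scene: GroundTruthScene, path: str | Path) -> tuple[Path, Path]:
    """Write channels as a two-page TIFF and the truth as a JSON sidecar."""
    import tifffile

    path = Path(path)
    dapi, marker = render_channels(scene)
    tifffile.imwrite(path, np.stack([dapi.pixels, marker.pixels]))
    truth = {
        "image_shape": list(scene.image_shape),
        "marker": scene.marker,
        "pixel_size_um": scene.pixel_size_um,
        "seed": scene.seed,
        "bleed_coefficient": scene.bleed_coefficient,
        "nuclei": scene.nuclei,
        "cells": [
            {
                "soma_center": list(c.soma_center),
                "marker": c.marker,
                "colocalized_nucleus": c.colocalized_nucleus,
                "junction_count": c.junction_count,
                "branch_lengths_px": c.branch_lengths_px.tolist(),
            }
            for c in scene.cells
        ],
        "true_mean_branch_length_um": scene.true_mean_branch_length_um(),
        "true_junction_count": scene.true_junction_count(),
        "true_percent_positive": scene.true_percent_positive(),
    }
    sidecar = path.with_suffix(".truth.json")
    sidecar.write_text(json.dumps(truth, indent=2))
    return path, sidecar


def load_scene(path: str | Path) -> tuple[ChannelImage, ChannelImage, dict]:
    """Read back a saved scene: (DAPI, marker, truth dict)."""
    import tifffile

    path = Path(path)
    pages = tifffile.imread(path)
    truth = json.loads(path.with_suffix(".truth.json").read_text())
    px = truth["pixel_size_um"]
    bd = 8 if pages.dtype == np.uint8 else 16
    dapi = ChannelImage(pages[0], channel="DAPI", pixel_size_um=px, bit_depth=bd)
    marker = ChannelImage(pages[1], channel=truth["marker"], pixel_size_um=px, bit_depth=bd)
    return dapi, marker, truth
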