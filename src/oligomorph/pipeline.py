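"""End-to-end orchestration: simulate/load -> preprocess -> segment ->
morphometrics -> statistics, with per-image fault isolation and reproducible
seeding."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from oligomorph import __version__
from oligomorph.config import RunConfig
from oligomorph.image import ChannelImage
from oligomorph.morphometrics import (
    MorphometricRecord,
    average_cell_size,
    detect_ridges,
    percent_positive,
    skeletonize_mask,
    summarize_morphology,
)
from oligomorph.preprocess import run_chain
from oligomorph.segment import (
    apply_binary_ops,
    extract_rois,
    filter_bleedthrough,
    filter_by_solidity,
    huang_threshold,
    rois_to_mask,
)
from oligomorph.stats import analyze_table
from oligomorph.synthetic import SceneParams, generate_scene, render_channels

log = logging.getLogger(__name__)


@dataclass
class FieldResult:
    records: list[MorphometricRecord]
    n_dapi: int
    n_marker_kept: int
    marker_pre: np.ndarray | None = None  # preprocessed marker pixels (QC)
    kept_mask: np.ndarray | None = None  # bleed-filtered cell footprint (QC)


@dataclass
class RunResult:
    records: pd.DataFrame  # wide, one row per fov x method
    table: pd.DataFrame  # tidy group/line/fov/metric/value
    stats: dict
    n_failed: int
    outdir: Path | None


def analyze_field(dapi: ChannelImage, marker: ChannelImage, config: RunConfig,
                  group: str = "", line_id: str = "", fov_id: str = "") -> FieldResult:
    """Measure one field of view (a DAPI + marker channel pair)."""
    seg = config["segment"]
    morph = config["morphometrics"]
    pp = config["preprocess"]

    dapi_p = run_chain(dapi, params=pp)
    marker_p = run_chain(marker, params=pp)

    _, dapi_mask = huang_threshold(dapi_p, seg["threshold_variant"]["DAPI"])
    dapi_mask = apply_binary_ops(dapi_mask, seg["binary_ops"]["DAPI"])
    dapi_rois = extract_rois(dapi_mask, seg["min_area_px"])

    _, marker_mask = huang_threshold(marker_p, seg["threshold_variant"][marker.channel])
    ops = seg["binary_ops"].get(marker.channel, [])
    if ops:
        marker_mask = apply_binary_ops(marker_mask, ops)
    marker_rois = extract_rois(marker_mask, seg["min_area_px"])

    if marker.channel == "MBP":  # bleed-through correction filters
        marker_rois = filter_by_solidity(marker_rois, seg["solidity_cutoff"])
        marker_rois = filter_bleedthrough(marker_rois, dapi_rois, seg["overlap_cutoff"])

    kept_mask = rois_to_mask(marker_rois, marker_mask.shape)
    kept_mask.pixel_size_um = marker.pixel_size_um

    pct = percent_positive(marker_rois, dapi_rois)
    n_cells = _count_positive_cells(marker_rois, dapi_rois)
    cell_count = n_cells if n_cells > 0 else len(marker_rois)
    size = average_cell_size(kept_mask, cell_count) if cell_count else math.nan

    # restrict morphometrics to the bleed-filtered cell footprint
    region = ndi.binary_dilation(kept_mask.pixels, iterations=3)
    masked_marker = marker_p.with_pixels(
        np.where(region, marker_p.pixels, 0), "mask_to_kept_rois")

    records = []
    for method in morph["methods"]:
        rec = MorphometricRecord(group=group, line_id=line_id, fov_id=fov_id,
                                 marker=marker.channel, method=method,
                                 percent_positive=pct, avg_cell_size=size)
        if cell_count == 0:
            rec.missing = True
            records.append(rec)
            continue
        if method == "ridge":
            lines = detect_ridges(masked_marker, sigma=morph["sigma"],
                                  low_contrast=morph["low_contrast"],
                                  high_contrast=morph["high_contrast"],
                                  prune_px=morph["prune_px"])
            abl, ajn = summarize_morphology(lines, cell_count, "ridge")
        else:
            graph = skeletonize_mask(kept_mask, prune_px=morph["prune_px"])
            abl, ajn = summarize_morphology(graph, cell_count, "skeleton")
        rec.avg_branch_length = abl
        rec.avg_junction_number = ajn
        rec.missing = math.isnan(abl)
        records.append(rec)
    return FieldResult(records, n_dapi=len(dapi_rois), n_marker_kept=len(marker_rois),
                       marker_pre=np.asarray(marker_p.pixels),
                       kept_mask=kept_mask.pixels)


def _count_positive_cells(marker_rois, dapi_rois) -> int:
    centroids = [(int(round(r.centroid[0])), int(round(r.centroid[1]))) for r in dapi_rois]
    n = 0
    for roi in marker_rois:
        pix = {(int(r), int(c)) for r, c in roi.coords}
        if any(ctr in pix for ctr in centroids):
            n += 1
    return n


def _simulated_fields(config: RunConfig):
    """Yield (group, line_id, fov_id, dapi, marker) for the simulated cohort."""
    sim = config["simulation"]
    rng = np.random.default_rng([config.seed, 0xF1E1D])
    for g_idx, group in enumerate(("Ctrl", "SCZ")):
        for li in range(int(sim["n_lines_per_group"])):
            line_id = f"{group}_{li + 1:02d}"
            line_scale = float(np.exp(rng.normal(0.0, sim["line_scale_sd"])))
            if g_idx == 1:
                line_scale *= 1.0 + float(sim["branch_length_effect"])
            for fi in range(int(sim["n_fov_per_line"])):
                fov_id = f"fov{fi + 1:02d}"
                params = SceneParams(
                    image_shape=tuple(sim["image_shape"]),
                    n_nuclei=int(sim["n_nuclei"]),
                    n_cells=int(sim["n_cells"]),
                    tree_segment_len=tuple(sim["segment_len_range"])
                    if sim.get("segment_len_range") else None,
                    marker=sim["marker"],
                    bleed_coefficient=float(sim["bleed_coefficient"]),
                    illumination_amplitude=float(sim["illumination_amplitude"]),
                    photon_scale=float(sim["photon_scale"]),
                    read_sd=float(sim["read_sd"]),
                    length_scale=line_scale,
                )
                scene_seed = int(np.random.default_rng(
                    [config.seed, g_idx, li, fi]).integers(0, 2**31 - 1))
                scene = generate_scene(params, seed=scene_seed)
                dapi, marker = render_channels(scene)
                yield group, line_id, fov_id, dapi, marker


def _manifest_fields(config: RunConfig):
    """Pair DAPI and marker rows of the manifest per (group, line, fov)."""
    import tifffile

    mf = pd.read_csv(config["manifest"])
    for (group, line, fov), sub in mf.groupby(["group", "line", "fov"], sort=True):
        by_channel = {row["channel"]: row for _, row in sub.iterrows()}
        dapi_row = by_channel["DAPI"]
        marker_name = "MBP" if "MBP" in by_channel else "O4"
        marker_row = by_channel[marker_name]
        px = float(dapi_row.get("pixel_size_um", 1.0))
        dapi = ChannelImage(tifffile.imread(dapi_row["path"]), channel="DAPI",
                            pixel_size_um=px)
        marker = ChannelImage(tifffile.imread(marker_row["path"]),
                              channel=marker_name, pixel_size_um=px)
        yield str(group), str(line), str(fov), dapi, marker


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage; failing fields are recorded as missing, not fatal."""
    t0 = time.time()
    fields = _simulated_fields(config) if config["mode"] == "simulate" \
        else _manifest_fields(config)
    all_records: list[MorphometricRecord] = []
    n_failed = 0
    outdir = Path(config["outdir"]) if config["outdir"] else None
    overlay_dir = None
    if outdir is not None and config["write_overlays"]:
        overlay_dir = outdir / "overlays"
        overlay_dir.mkdir(parents=True, exist_ok=True)
    for group, line_id, fov_id, dapi, marker in fields:
        t1 = time.time()
        try:
            fr = analyze_field(dapi, marker, config, group, line_id, fov_id)
            all_records.extend(fr.records)
            if overlay_dir is not None:
                _write_overlay(overlay_dir / f"{group}_{line_id}_{fov_id}.png", fr)
            log.info("field %s/%s/%s: %d DAPI, %d marker ROIs kept (%.2fs)",
                     group, line_id, fov_id, fr.n_dapi, fr.n_marker_kept,
                     time.time() - t1)
        except Exception as exc:  # noqa: BLE001 - per-image fault isolation
            n_failed += 1
            log.warning("field %s/%s/%s failed (%s); recording missing values",
                        group, line_id, fov_id, exc)
            for method in config["morphometrics"]["methods"]:
                all_records.append(MorphometricRecord(
                    group=group, line_id=line_id, fov_id=fov_id,
                    marker=marker.channel, method=method, missing=True))

    records = pd.DataFrame([dataclasses.asdict(r) for r in all_records])
    table = records_to_table(records)
    stats: dict = analyze_table(
        table, alpha=config["stats"]["alpha"],
        df_method=config["stats"]["df_method"],
        transform=config["stats"]["transform"],
    ) if not table.empty else {}

    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        records.to_csv(outdir / "measurements.csv", index=False)
        table.to_csv(outdir / "measurements_tidy.csv", index=False)
        provenance = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": hashlib.sha256(
                json.dumps(config.raw, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "elapsed_s": round(time.time() - t0, 2),
            "n_failed": n_failed,
        }
        with open(outdir / "stats.json", "w") as fh:
            json.dump({"provenance": provenance, "results": stats}, fh, indent=2)
        with open(outdir / "config.json", "w") as fh:
            json.dump(config.raw, fh, indent=2, default=str)
    return RunResult(records=records, table=table, stats=stats,
                     n_failed=n_failed, outdir=outdir)


def _write_overlay(path: Path, fr: FieldResult) -> None:
    """QC PNG: preprocessed marker in grey, kept-cell footprint outline in red."""
    import matplotlib.image as mpimg

    if fr.marker_pre is None or fr.kept_mask is None:
        return
    grey = fr.marker_pre.astype(float)
    grey = grey / max(grey.max(), 1.0)
    rgb = np.stack([grey, grey, grey], axis=-1)
    outline = fr.kept_mask & ~ndi.binary_erosion(fr.kept_mask)
    rgb[outline] = (1.0, 0.1, 0.1)
    mpimg.imsave(path, rgb)


def records_to_table(records: pd.DataFrame) -> pd.DataFrame:
    """Melt wide per-fov records into the tidy stats input table.

    Method-dependent metrics get a ``<metric>.<method>`` name; positivity and
    size are method-independent and taken from the first method's rows.
    """
    if records.empty:
        return pd.DataFrame(columns=["group", "line", "fov", "metric", "value"])
    rows = []
    first_method = records["method"].iloc[0]
    for _, r in records.iterrows():
        key = (r["group"], r["line_id"], r["fov_id"])
        if r["method"] == first_method:
            rows.append((*key, "percent_positive", r["percent_positive"]))
            rows.append((*key, "avg_cell_size", r["avg_cell_size"]))
        rows.append((*key, f"avg_branch_length.{r['method']}", r["avg_branch_length"]))
        rows.append((*key, f"avg_junction_number.{r['method']}", r["avg_junction_number"]))
    return pd.DataFrame(rows, columns=["group", "line", "fov", "metric", "value"])
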