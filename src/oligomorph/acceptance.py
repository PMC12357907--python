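"""Self-contained acceptance-study computations.

Each ``criterion_*`` function recomputes one acceptance property from scratch
(generating its own synthetic inputs) and returns plain numbers; the pytest
acceptance suite asserts on them and ``scripts/acceptance.py`` serializes
them.  Oracles used here are deliberately independent, literal
re-implementations of the quantities they check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

from oligomorph.config import validate_config
from oligomorph.image import ChannelImage
from oligomorph.morphometrics import detect_ridges, skeletonize_mask, summarize_morphology
from oligomorph.pipeline import run_pipeline
from oligomorph.preprocess import run_chain
from oligomorph.segment import (
    Roi,
    apply_binary_ops,
    extract_rois,
    filter_bleedthrough,
    filter_by_solidity,
    huang_threshold,
)
from oligomorph.stats import effective_tests_simplem, fit_mixed_anova, group_ttest_cohend
from oligomorph.synthetic import (
    CohortDesign,
    SceneParams,
    generate_scene,
    render_channels,
    simulate_measurements,
)


# ---------------------------------------------------------------------------
# criterion 1: Huang threshold vs exhaustive fuzzy-entropy oracle
# ---------------------------------------------------------------------------

def brute_force_huang(hist: np.ndarray) -> int:
    """Literal per-threshold fuzzy-entropy minimization (independent oracle)."""
    g = np.arange(256)
    nz = np.nonzero(hist)[0]
    span = max(int(nz[-1]) - int(nz[0]), 1)
    best_t, best_e = 0, math.inf
    for t in range(255):
        lo, hi = hist[: t + 1], hist[t + 1:]
        if lo.sum() == 0 or hi.sum() == 0:
            continue
        mu0 = (lo * g[: t + 1]).sum() / lo.sum()
        mu1 = (hi * g[t + 1:]).sum() / hi.sum()
        e = 0.0
        for gv in range(256):
            if hist[gv] == 0:
                continue
            mu = mu0 if gv <= t else mu1
            u = 1.0 / (1.0 + abs(gv - mu) / span)
            if 0.0 < u < 1.0:
                e += hist[gv] * (-u * math.log(u) - (1 - u) * math.log(1 - u))
        if e < best_e:
            best_e, best_t = e, t
    return best_t


def _random_bimodal_image(rng: np.random.Generator) -> np.ndarray:
    n1, n2 = rng.integers(100, 1500, 2)
    a = np.clip(rng.normal(rng.uniform(20, 110), rng.uniform(3, 30), n1), 0, 255)
    b = np.clip(rng.normal(rng.uniform(120, 240), rng.uniform(3, 30), n2), 0, 255)
    vals = np.concatenate([a, b]).astype(np.uint8)
    side = int(np.ceil(np.sqrt(vals.size)))
    img = np.full(side * side, vals[0], dtype=np.uint8)
    img[: vals.size] = vals
    return img.reshape(side, side)


def criterion_1_huang_oracle(seed: int, n_histograms: int = 100) -> dict:
    rng = np.random.default_rng([seed, 1])
    mismatches = 0
    for _ in range(n_histograms):
        px = _random_bimodal_image(rng)
        if px.min() == px.max():
            continue
        t, _ = huang_threshold(ChannelImage(px, channel="MBP"), "huang")
        hist = np.bincount(px.ravel(), minlength=256)
        mismatches += t != brute_force_huang(hist)
    return {"mismatches": mismatches, "n": n_histograms}


# ---------------------------------------------------------------------------
# criterion 2: strict-inequality filter contracts at the printed cut-offs
# ---------------------------------------------------------------------------

def _fixture_roi(coords, shape, solidity):
    coords = np.asarray(coords)
    return Roi(label=1, coords=coords, image_shape=shape, area_px=len(coords),
               centroid=tuple(coords.mean(axis=0)), solidity=solidity,
               bbox=(0, 0, *shape))


def criterion_2_filter_boundaries(seed: int = 0) -> dict:
    shape = (20, 20)
    checks = []
    checks.append(len(filter_by_solidity([_fixture_roi([(0, 0)], shape, 0.65)])) == 1)
    checks.append(len(filter_by_solidity([_fixture_roi([(0, 0)], shape, 0.70)])) == 0)
    checks.append(len(filter_by_solidity([_fixture_roi([(0, 0)], shape, 1.0)])) == 0)

    ref = [_fixture_roi([(r, c) for r in range(10) for c in range(10)], shape, 1.0)]
    inside = [(r, c) for r in range(10) for c in range(10)]
    outside = [(r, c) for r in range(10, 20) for c in range(10)]
    target59 = _fixture_roi(inside[:59] + outside[:41], shape, 0.5)
    target60 = _fixture_roi(inside[:60] + outside[:40], shape, 0.5)
    checks.append(len(filter_bleedthrough([target59], ref, 0.6)) == 1)
    checks.append(len(filter_bleedthrough([target60], ref, 0.6)) == 0)
    checks.append(len(filter_bleedthrough(
        [_fixture_roi(inside[:5], shape, 0.5)], ref, 0.6)) == 0)  # fully inside
    checks.append(len(filter_bleedthrough(
        [_fixture_roi(outside[:5], shape, 0.5)], ref, 0.6)) == 1)  # disjoint
    return {"failures": sum(not c for c in checks), "n": len(checks)}


# ---------------------------------------------------------------------------
# criterion 3: morphometric ground-truth recovery + backend concordance
# ---------------------------------------------------------------------------

def _measure_scene(scene):
    _, marker = render_channels(scene)
    pre = run_chain(marker)
    _, mask = huang_threshold(pre, "huang2")
    lines = detect_ridges(pre)
    graph = skeletonize_mask(mask)
    n = len(scene.cells)
    ridge = summarize_morphology(lines, n, "ridge")
    skel = summarize_morphology(graph, n, "skeleton")
    return ridge, skel


def criterion_3_recovery(seed: int, n_scenes: int = 50) -> dict:
    scales = np.linspace(0.75, 1.4, n_scenes)
    ratios = {"ridge_bl": [], "skel_bl": [], "ridge_jn": [], "skel_jn": []}
    ridge_bl, skel_bl = [], []
    for i, scale in enumerate(scales):
        scene = generate_scene(SceneParams(length_scale=float(scale)),
                               seed=seed * 1000 + i)
        (rbl, rjn), (sbl, sjn) = _measure_scene(scene)
        tb = scene.true_mean_branch_length_um()
        tj = scene.true_junctions_per_cell()
        ratios["ridge_bl"].append(rbl / tb)
        ratios["skel_bl"].append(sbl / tb)
        ratios["ridge_jn"].append(rjn / tj)
        ratios["skel_jn"].append(sjn / tj)
        ridge_bl.append(rbl)
        skel_bl.append(sbl)
    mean_ratios = {k: float(np.mean(v)) for k, v in ratios.items()}
    rho = float(sps.spearmanr(ridge_bl, skel_bl).statistic)
    worst = max(abs(r - 1.0) for r in mean_ratios.values())
    return {"mean_ratios": mean_ratios, "worst_ratio_error": worst,
            "spearman": rho, "n": n_scenes}


# ---------------------------------------------------------------------------
# criterion 4: bleed-through rescue by the solidity + overlap filter pair
# ---------------------------------------------------------------------------

def criterion_4_bleedthrough_rescue(seed: int, n_scenes: int = 8) -> dict:
    cfg = validate_config({})
    seg = cfg["segment"]
    tot_art = rem_art = tot_true = kept_true = 0
    for i in range(n_scenes):
        p = SceneParams(n_nuclei=10, n_cells=5, bleed_coefficient=0.4,
                        photon_scale=20.0, read_sd=1.5)
        scene = generate_scene(p, seed=seed * 1000 + i)
        dapi, marker = render_channels(scene)
        dp, mp = run_chain(dapi), run_chain(marker)
        _, dmask = huang_threshold(dp, "huang2")
        dmask = apply_binary_ops(dmask, seg["binary_ops"]["DAPI"])
        drois = extract_rois(dmask, seg["min_area_px"])
        _, mmask = huang_threshold(mp, "huang2")
        mrois = extract_rois(mmask, seg["min_area_px"])

        kept = filter_bleedthrough(filter_by_solidity(mrois, seg["solidity_cutoff"]),
                                   drois, seg["overlap_cutoff"])
        kept_ids = {id(r) for r in kept}
        soma = {(round(c.soma_center[0]), round(c.soma_center[1])) for c in scene.cells}
        coloc = {c.colocalized_nucleus for c in scene.cells
                 if c.colocalized_nucleus is not None}
        free_nuclei = {(round(n["center"][0]), round(n["center"][1]))
                       for j, n in enumerate(scene.nuclei) if j not in coloc}
        for roi in mrois:
            pix = {(int(a), int(b)) for a, b in roi.coords}
            if pix & soma:
                tot_true += 1
                kept_true += id(roi) in kept_ids
            elif pix & free_nuclei:
                tot_art += 1
                rem_art += id(roi) not in kept_ids
    return {
        "artifact_removal_pct": 100.0 * rem_art / max(tot_art, 1),
        "true_retention_pct": 100.0 * kept_true / max(tot_true, 1),
        "n_artifacts": tot_art,
        "n_true": tot_true,
    }


# ---------------------------------------------------------------------------
# criterion 5: mixed-model type-I calibration and sensitivity ordering
# ---------------------------------------------------------------------------

def criterion_5_mixed_calibration(seed: int, reps: int = 1000) -> dict:
    null_hits = 0
    for i in range(reps):
        d = CohortDesign(n_lines_per_group=7, n_fov_per_line=10, group_effect=0.0,
                         line_sd=0.1, fov_sd=0.15, metrics=("m",),
                         seed=seed * 10_000_000 + i)
        null_hits += fit_mixed_anova(simulate_measurements(d), "m").p_value < 0.05
    mixed_hits = ttest_hits = 0
    for i in range(reps):
        d = CohortDesign(n_lines_per_group=7, n_fov_per_line=10, group_effect=0.1,
                         line_sd=0.1, fov_sd=0.15, metrics=("m",),
                         seed=seed * 10_000_000 + 5_000_000 + i)
        t = simulate_measurements(d)
        mixed_hits += fit_mixed_anova(t, "m").p_value < 0.05
        ttest_hits += group_ttest_cohend(t, "m").p < 0.05
    return {
        "type_I_error": null_hits / reps,
        "mixed_power": mixed_hits / reps,
        "ttest_power": ttest_hits / reps,
        "n": reps,
    }


# ---------------------------------------------------------------------------
# criterion 6: simpleM oracle fixtures
# ---------------------------------------------------------------------------

def criterion_6_simplem(seed: int) -> dict:
    rng = np.random.default_rng([seed, 6])
    indep = effective_tests_simplem(rng.normal(size=(2000, 10))).meff
    x = rng.normal(size=500)
    ident = effective_tests_simplem(np.tile(x[:, None], (1, 10))).meff
    a, b = rng.normal(size=(2, 400))
    blocks_X = np.column_stack([np.tile(a[:, None], (1, 5)),
                                np.tile(b[:, None], (1, 5))])
    blocks = effective_tests_simplem(blocks_X).meff
    # brute-force check on the block design's exact correlation matrix
    eig = np.sort(np.linalg.eigvalsh(np.corrcoef(blocks_X, rowvar=False)))[::-1]
    cum = np.cumsum(np.clip(eig, 0, None))
    brute_blocks = int(np.searchsorted(cum, 0.995 * cum[-1] - 1e-12) + 1)
    return {"meff_independent": indep, "meff_identical": ident,
            "meff_blocks": blocks, "meff_blocks_bruteforce": brute_blocks}


# ---------------------------------------------------------------------------
# criterion 7: end-to-end demo, effect run vs matched null run
# ---------------------------------------------------------------------------

def criterion_7_demo(seed: int, n_seeds: int = 20, effect: float = 0.5) -> dict:
    hits = 0
    for i in range(n_seeds):
        run_seed = seed * 1000 + i
        results = {}
        for name, eff in (("effect", effect), ("null", 0.0)):
            cfg = validate_config({
                "seed": run_seed,
                "simulation": {"branch_length_effect": eff},
            })
            res = run_pipeline(cfg)
            mm = res.stats["metrics"]["avg_branch_length.ridge"]["mixed_anova"]
            results[name] = (mm["estimate"], mm["p"])
        hits += results["effect"][0] > 0 and results["effect"][1] < results["null"][1]
    return {"success_pct": 100.0 * hits / n_seeds, "n": n_seeds}
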