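import math

import numpy as np
import pytest

from oligomorph.image import ChannelImage
from oligomorph.morphometrics import (
    LineSet,
    average_cell_size,
    detect_ridges,
    percent_positive,
    skeletonize_mask,
    summarize_morphology,
)
from oligomorph.morphometrics.summary import cluster_point_count
from oligomorph.segment import BinaryMask, Roi, extract_rois, huang_threshold
from oligomorph.synthetic import SceneParams, generate_scene, render_channels
from oligomorph.preprocess import run_chain
from tests.conftest import make_image


def _roi(coords, shape=(64, 64)):
    coords = np.asarray(coords)
    return Roi(label=1, coords=coords, image_shape=shape, area_px=len(coords),
               centroid=tuple(coords.mean(axis=0)), solidity=1.0,
               bbox=(0, 0, *shape))


def _disc_roi(center, radius, shape=(64, 64)):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    m = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return _roi(np.argwhere(m), shape)


class TestPercentPositive:
    def test_no_marker_rois(self):
        dapi = [_disc_roi((10, 10), 3) for _ in range(5)]
        assert percent_positive([], dapi) == 0.0

    def test_all_colocalized_caps_at_100(self):
        dapi = [_disc_roi((20, 20), 3), _disc_roi((40, 40), 3)]
        markers = [_disc_roi((20, 20), 6), _disc_roi((40, 40), 6),
                   _disc_roi((20, 20), 8)]
        assert percent_positive(markers, dapi) == 100.0

    def test_zero_dapi_missing(self):
        assert math.isnan(percent_positive([_disc_roi((5, 5), 2)], []))

    def test_six_of_ten_scene_truth(self):
        # generator truth: 10 nuclei, 6 colocalized cells -> 60%
        p = SceneParams(image_shape=(320, 320), n_nuclei=10, n_cells=6,
                        colocalized_fraction=1.0)
        s = generate_scene(p, seed=9)
        assert s.true_percent_positive() == 60.0
        dapi_rois = [_disc_roi((round(n["center"][0]), round(n["center"][1])), 3,
                               s.image_shape) for n in s.nuclei]
        marker_rois = [_disc_roi((round(c.soma_center[0]), round(c.soma_center[1])), 6,
                                 s.image_shape) for c in s.cells]
        assert percent_positive(marker_rois, dapi_rois) == 60.0

    def test_bounded(self, rng):
        for _ in range(20):
            n_d, n_m = rng.integers(1, 6), rng.integers(0, 6)
            dapi = [_disc_roi(tuple(rng.integers(5, 58, 2)), 2) for _ in range(n_d)]
            marker = [_disc_roi(tuple(rng.integers(5, 58, 2)), 4) for _ in range(n_m)]
            v = percent_positive(marker, dapi)
            assert 0.0 <= v <= 100.0


class TestAverageCellSize:
    def test_arithmetic(self):
        m = np.zeros((40, 40), bool)
        m[:30, :30] = True  # 900 px
        assert average_cell_size(BinaryMask(m), 9) == 100.0

    def test_empty_mask(self):
        assert average_cell_size(BinaryMask(np.zeros((10, 10), bool)), 5) == 0.0

    def test_zero_cells_missing(self):
        assert math.isnan(average_cell_size(BinaryMask(np.ones((4, 4), bool)), 0))

    def test_disc_scene_recovery(self):
        # discs of radius 10 rendered at 200 grey, standard threshold chain
        rr, cc = np.mgrid[0:200, 0:200]
        img = np.zeros((200, 200))
        centers = [(40, 40), (40, 150), (150, 40), (150, 150), (100, 100)]
        for r0, c0 in centers:
            img[(rr - r0) ** 2 + (cc - c0) ** 2 <= 100] = 200.0
        rng = np.random.default_rng(0)
        img += rng.normal(0, 3, img.shape)
        chan = make_image(np.clip(img, 0, 255).astype(np.uint8), channel="O4")
        pre = run_chain(chan, steps=("to_8bit", "median_smooth"))
        _, mask = huang_threshold(pre, "huang")
        rois = extract_rois(mask)
        size = average_cell_size(mask, len(rois))
        assert size == pytest.approx(math.pi * 100, rel=0.15)


class TestDetectRidges:
    def test_blank_image(self):
        ls = detect_ridges(make_image(np.zeros((64, 64), dtype=np.uint8)))
        assert ls.polylines == [] and ls.junction_count == 0

    def test_single_gaussian_line_subpixel(self):
        rr = np.arange(128)[:, None].astype(float)
        true_row = 63.0
        img = 150.0 * np.exp(-((rr - true_row) ** 2) / (2 * 1.3**2))
        img = np.tile(img, (1, 128))[:, :]
        chan = make_image(np.round(img).astype(np.uint8))
        ls = detect_ridges(chan, sigma=1.5, low_contrast=2, high_contrast=10)
        assert len(ls.polylines) == 1
        poly = ls.polylines[0]
        interior = poly[(poly[:, 1] > 10) & (poly[:, 1] < 118)]
        rms = np.sqrt(np.mean((interior[:, 0] - true_row) ** 2))
        assert rms < 0.5
        assert ls.lengths_px[0] > 80

    def test_crossing_lines_junction(self):
        rr, cc = np.mgrid[0:101, 0:101].astype(float)
        d1 = np.abs(rr - cc) / np.sqrt(2)  # diagonal
        d2 = np.abs(rr + cc - 100) / np.sqrt(2)  # anti-diagonal
        img = 150.0 * (np.exp(-(d1**2) / (2 * 1.3**2)) + np.exp(-(d2**2) / (2 * 1.3**2)))
        ls = detect_ridges(make_image(np.round(np.clip(img, 0, 255)).astype(np.uint8)),
                           sigma=1.5, low_contrast=2, high_contrast=10)
        assert ls.junction_count >= 1
        dists = np.hypot(*(ls.junction_points - np.array([50.0, 50.0])).T)
        assert dists.min() <= 2.0

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            detect_ridges(make_image(np.zeros((64, 64))), low_contrast=5, high_contrast=2)


class TestSkeletonizeMask:
    def test_horizontal_line(self):
        m = np.zeros((9, 60), bool)
        m[4, 5:55] = True
        g = skeletonize_mask(BinaryMask(m))
        assert g.n_branches == 1
        assert g.junction_count == 0
        assert g.branch_lengths_px[0] == pytest.approx(49.0)

    def test_y_shape(self):
        m = np.zeros((64, 64), bool)
        m[32, 32 - 20:33] = True  # west arm
        for i in range(20):  # two diagonal arms
            m[32 - i, 32 + i] = True
            m[32 + i, 32 + i] = True
        g = skeletonize_mask(BinaryMask(m))
        assert g.junction_count == 1
        assert g.n_branches == 3

    def test_filled_disc_collapses(self):
        rr, cc = np.mgrid[0:64, 0:64]
        m = (rr - 32) ** 2 + (cc - 32) ** 2 <= 20**2
        g = skeletonize_mask(BinaryMask(m), prune_px=4)
        assert g.total_length_um < 2 * 40
        assert g.junction_count == 0

    def test_empty_mask(self):
        g = skeletonize_mask(BinaryMask(np.zeros((16, 16), bool)))
        assert g.n_branches == 0 and g.junction_count == 0

    def test_diagonal_step_length(self):
        m = np.zeros((20, 20), bool)
        for i in range(10):
            m[i + 2, i + 2] = True
        g = skeletonize_mask(BinaryMask(m))
        assert g.branch_lengths_px[0] == pytest.approx(9 * np.sqrt(2))

    def test_pixel_size_scaling(self):
        m = np.zeros((9, 40), bool)
        m[4, 5:35] = True
        g1 = skeletonize_mask(BinaryMask(m, pixel_size_um=1.0))
        g2 = skeletonize_mask(BinaryMask(m, pixel_size_um=2.0))
        assert g2.branch_lengths_um[0] == pytest.approx(2 * g1.branch_lengths_um[0])
        assert g1.junction_count == g2.junction_count


class TestSummarize:
    def _lineset(self, lengths, junctions):
        polys = [np.column_stack([np.full(2, 10.0 * i), [0.0, ln]])
                 for i, ln in enumerate(lengths)]
        return LineSet(polylines=polys, widths=[np.ones(2)] * len(polys),
                       junction_points=np.asarray(junctions, dtype=float).reshape(-1, 2))

    def test_arithmetic(self):
        ls = self._lineset([10, 20, 30], [[0, 0], [50, 50]])
        abl, ajn = summarize_morphology(ls, 4, "ridge")
        assert abl == pytest.approx(20.0)
        assert ajn == pytest.approx(0.5)

    def test_no_branches_missing(self):
        ls = LineSet()
        abl, ajn = summarize_morphology(ls, 3, "ridge")
        assert math.isnan(abl) and math.isnan(ajn)

    def test_zero_cells_missing(self):
        abl, ajn = summarize_morphology(self._lineset([5], []), 0, "ridge")
        assert math.isnan(abl) and math.isnan(ajn)

    def test_junction_clustering(self):
        assert cluster_point_count([(0, 0), (1, 1), (30, 30)], radius=6) == 2
        assert cluster_point_count([], radius=6) == 0
        # chained linkage merges transitively
        assert cluster_point_count([(0, 0), (5, 0), (10, 0)], radius=6) == 1

    def test_bad_method(self):
        with pytest.raises(ValueError):
            summarize_morphology(LineSet(), 1, "contour")


class TestGroundTruthRecovery:
    def _measure(self, scene):
        dapi, marker = render_channels(scene)
        pre = run_chain(marker)
        _, mask = huang_threshold(pre, "huang2")
        ls = detect_ridges(pre)
        sg = skeletonize_mask(mask)
        n = len(scene.cells)
        return summarize_morphology(ls, n, "ridge"), summarize_morphology(sg, n, "skeleton")

    def test_recovery_within_20pct(self):
        ratios = {"ridge_bl": [], "skel_bl": [], "ridge_jn": [], "skel_jn": []}
        for seed in range(10):
            s = generate_scene(SceneParams(), seed=seed)
            (rbl, rjn), (sbl, sjn) = self._measure(s)
            tb, tj = s.true_mean_branch_length_um(), s.true_junctions_per_cell()
            ratios["ridge_bl"].append(rbl / tb)
            ratios["skel_bl"].append(sbl / tb)
            ratios["ridge_jn"].append(rjn / tj)
            ratios["skel_jn"].append(sjn / tj)
        for key, vals in ratios.items():
            assert 0.8 <= np.mean(vals) <= 1.2, (key, np.mean(vals))

    def test_group_effect_recovery(self):
        # +8% true branch length; each replicate pools the branches of 16
        # paired single-cell scenes per group; the recovered group difference
        # must be positive in >= 90% of 50 seeded replicates (both methods)
        def branch_pools(scene):
            dapi, marker = render_channels(scene)
            pre = run_chain(marker)
            _, mask = huang_threshold(pre, "huang2")
            return detect_ridges(pre).lengths_um, skeletonize_mask(mask).branch_lengths_um

        hits_r = hits_s = 0
        reps, m = 50, 16
        for rep in range(reps):
            pools = [[], [], [], []]
            for i in range(m):
                seed = rep * 100 + i
                kw = dict(image_shape=(160, 160), n_cells=1, n_nuclei=2)
                base = generate_scene(SceneParams(**kw), seed=seed)
                # same seed: identical geometry, branch lengths scaled by 1.08
                boosted = generate_scene(SceneParams(**kw, length_scale=1.08), seed=seed)
                for pool, vals in zip(pools, [*branch_pools(base), *branch_pools(boosted)]):
                    pool.append(vals)
            rb0, sb0, rb1, sb1 = (np.concatenate(p) for p in pools)
            hits_r += rb1.mean() > rb0.mean()
            hits_s += sb1.mean() > sb0.mean()
        assert hits_r >= 0.9 * reps
        assert hits_s >= 0.9 * reps
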