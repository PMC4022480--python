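"""Unit tests for the rendering and segmentation/quantification chain."""

import numpy as np
import pytest
from skimage.filters import threshold_otsu as skimage_otsu

from cyberloop.imaging import (
    ImagePair,
    SyntheticScene,
    convex_hull_regions,
    hough_circles,
    match_detections,
    otsu_threshold,
    random_scene,
    render_scene,
    segment_and_quantify,
)


class TestRender:
    def test_empty_scene_is_background_noise(self):
        scene = SyntheticScene(shape=(64, 64), cells=np.empty((0, 4)),
                               noise_sd=0.01, seed=4)
        pair = render_scene(scene)
        assert abs(pair.phase.mean() - scene.background_phase) < 0.01
        assert pair.phase.std() < 0.02

    def test_single_cell_single_component(self):
        scene = SyntheticScene(shape=(64, 64),
                               cells=[[32.0, 32.0, 7.0, 0.5]],
                               noise_sd=0.0, seed=0)
        pair = render_scene(scene)
        from skimage.measure import label

        fg = pair.phase < otsu_threshold(pair.phase)
        assert label(fg).max() == 1

    def test_same_seed_identical_rasters(self):
        scene = random_scene(20, seed=5, shape=(128, 128))
        a = render_scene(scene)
        b = render_scene(scene)
        np.testing.assert_array_equal(a.phase, b.phase)
        np.testing.assert_array_equal(a.fluo, b.fluo)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            ImagePair(np.zeros((4, 4)), np.zeros((5, 5)))


class TestOtsu:
    def test_two_level_image_exhaustive_oracle(self):
        """Classification agrees with exhaustive search over candidate
        thresholds on a bimodal image."""
        img = np.array([10.0] * 60 + [200.0] * 40)
        t = otsu_threshold(img)
        assert 10.0 < t < 200.0

        # exhaustive between-class variance over all candidate cuts
        values = np.sort(img)
        best, best_cut = -1.0, None
        for cut in np.unique(values)[:-1]:
            lo = values[values <= cut]
            hi = values[values > cut]
            w0, w1 = len(lo) / len(values), len(hi) / len(values)
            v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
            if v > best:
                best, best_cut = v, cut
        assert np.array_equal(img > t, img > best_cut)

    def test_matches_skimage_classification(self):
        """Independent cross-check: same pixel partition as the
        library implementation on a noisy bimodal image."""
        rng = np.random.default_rng(0)
        img = np.concatenate([rng.normal(0.2, 0.03, 3000),
                              rng.normal(0.7, 0.05, 1500)])
        ours = otsu_threshold(img)
        theirs = skimage_otsu(img, nbins=4096)
        assert np.mean((img > ours) != (img > theirs)) < 0.001

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((8, 8), 3.0))

    def test_shift_invariance_exact(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 255, size=(40, 40)).astype(float)
        c = 37.0
        assert otsu_threshold(img + c) == otsu_threshold(img) + c


class TestConvexHull:
    def test_filled_square_hull_is_corners(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        hulls = convex_hull_regions(mask)
        assert len(hulls) == 1
        corners = {(5, 5), (5, 14), (14, 5), (14, 14)}
        got = {tuple(map(int, v)) for v in hulls[0]}
        assert got == corners

    def test_l_shape_hull_larger_than_component(self):
        mask = np.zeros((30, 30), bool)
        mask[5:25, 5:10] = True
        mask[20:25, 5:25] = True
        hulls = convex_hull_regions(mask)
        from matplotlib.path import Path

        grid = np.array([(r, c) for r in range(30) for c in range(30)])
        inside = Path(hulls[0]).contains_points(grid, radius=0.1)
        assert inside.sum() > mask.sum()

    def test_matches_gift_wrapping_oracle(self, rng):
        """Hull vertices agree with a brute-force gift-wrapping march
        on the component's pixels."""
        mask = np.zeros((40, 40), bool)
        mask[10:30, 8:28] = rng.random((20, 20)) > 0.3
        # keep only the largest component's pixels for the oracle
        from skimage.measure import label, regionprops

        labels = label(mask, connectivity=2)
        region = max(regionprops(labels), key=lambda r: r.area)
        only = labels == region.label
        hull = convex_hull_regions(only)[0]

        def gift_wrap(points):
            pts_ = [tuple(p) for p in points]
            start = min(pts_)
            hull_pts = [start]
            cur = start
            while True:
                cand = pts_[0] if pts_[0] != cur else pts_[1 % len(pts_)]
                for p in pts_:
                    if p == cur:
                        continue
                    cross = ((cand[0] - cur[0]) * (p[1] - cur[1])
                             - (cand[1] - cur[1]) * (p[0] - cur[0]))
                    if cross < 0 or (cross == 0 and
                                     np.hypot(p[0] - cur[0], p[1] - cur[1])
                                     > np.hypot(cand[0] - cur[0],
                                                cand[1] - cur[1])):
                        cand = p
                hull_pts.append(cand)
                cur = cand
                if cand == start:
                    break
            return set(hull_pts[:-1])

        oracle = gift_wrap(np.argwhere(only))
        assert {tuple(map(int, v)) for v in hull} == oracle

    def test_empty_mask_empty_list(self):
        assert convex_hull_regions(np.zeros((10, 10), bool)) == []


class TestHough:
    def test_single_ring_localized(self):
        scene = SyntheticScene(shape=(64, 64),
                               cells=[[32.0, 32.0, 8.0, 0.5]],
                               noise_sd=0.0, seed=0)
        pair = render_scene(scene)
        fg = pair.phase < otsu_threshold(pair.phase)
        hulls = convex_hull_regions(fg)
        circles = hough_circles(pair.phase, hulls, 4.0, 12.0)
        assert circles.shape[0] == 1
        row, col, rad = circles[0]
        assert abs(row - 32.0) <= 1.0 and abs(col - 32.0) <= 1.0
        assert abs(rad - 8.0) <= 1.5

    def test_blank_image_no_circles(self):
        img = np.full((64, 64), 0.5)
        assert hough_circles(img, [], 4.0, 12.0).shape[0] == 0

    def test_two_separated_rings(self):
        scene = SyntheticScene(shape=(96, 96),
                               cells=[[28.0, 28.0, 7.0, 0.5],
                                      [68.0, 70.0, 9.0, 0.5]],
                               noise_sd=0.0, seed=0)
        pair = render_scene(scene)
        fg = pair.phase < otsu_threshold(pair.phase)
        circles = hough_circles(pair.phase, convex_hull_regions(fg),
                                4.0, 12.0)
        assert circles.shape[0] == 2

    def test_degenerate_radius_range(self):
        with pytest.raises(ValueError):
            hough_circles(np.zeros((10, 10)), [], 5.0, 5.0)


class TestPipeline:
    def test_crowded_scene_end_to_end(self):
        """~100 cells: nearly all found, centers within 2 px, quantified
        mean within 5% of the ground truth."""
        scene = random_scene(100, seed=12)
        res = segment_and_quantify(render_scene(scene))
        tp, fp, fn, errs = match_detections(scene.cells, res.circles)
        assert tp >= 95
        assert tp / (tp + fp) >= 0.95
        assert errs.max() <= 2.0
        assert res.mean_fluorescence == pytest.approx(
            scene.true_mean_fluorescence, rel=0.05)

    def test_uniform_intensity_quantified(self):
        scene = random_scene(30, seed=2, intensity_mean=0.5, intensity_cv=0.0,
                             noise_sd=0.01)
        res = segment_and_quantify(render_scene(scene))
        assert res.mean_fluorescence == pytest.approx(0.5, abs=0.02)

    def test_background_only_frame_flagged(self):
        pair = render_scene(SyntheticScene(shape=(64, 64),
                                           cells=np.empty((0, 4)),
                                           noise_sd=0.01, seed=1))
        res = segment_and_quantify(pair)
        assert res.flagged
        assert np.isnan(res.mean_fluorescence)

    def test_deterministic_under_seed(self):
        scene = random_scene(40, seed=8)
        a = segment_and_quantify(render_scene(scene))
        b = segment_and_quantify(render_scene(scene))
        np.testing.assert_array_equal(a.circles, b.circles)
        assert a.mean_fluorescence == b.mean_fluorescence

    def test_image_file_round_trip(self, tmp_path):
        scene = random_scene(10, seed=3, shape=(96, 96))
        pair = render_scene(scene)
        pair.write(tmp_path / "phase.png", tmp_path / "fluo.png")
        back = ImagePair.read(tmp_path / "phase.png", tmp_path / "fluo.png")
        assert back.phase.shape == pair.phase.shape
        # 16-bit quantization: better than 1e-4 per pixel
        assert np.max(np.abs(back.phase - np.clip(pair.phase, 0, 1))) < 1e-3
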