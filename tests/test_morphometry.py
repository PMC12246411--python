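"""ABCDE descriptor correctness against brute-force oracles and geometry."""

import numpy as np
import pytest

from dermaseq import morphometry as mm
from dermaseq.synthetic_lesions import LesionSpec, generate_lesion_mask, \
    render_lesion_image

from conftest import flat_rgb, rasterize_disk, rasterize_ellipse


def _random_blob_mask(seed, size=64):
    spec = LesionSpec(base_radius=10 + (seed % 12),
                      irregularity_level=(seed % 10) / 10.0,
                      asymmetry_level=(seed % 7) / 10.0,
                      image_size=(size, size))
    return generate_lesion_mask(spec, seed)


class TestSegmentation:
    def test_largest_component_wins(self):
        img = np.full((80, 80), 200, dtype=np.uint8)
        img[10:30, 10:30] = 60          # 400 px blob
        img[50:60, 50:60] = 60          # 100 px blob
        img3 = np.dstack([img] * 3)
        lesion = mm.segment_lesion(img3)
        assert lesion.mask[20, 20] and not lesion.mask[55, 55]
        assert lesion.area_AL == 400

    def test_uniform_image_raises(self):
        with pytest.raises(mm.NoLesionError):
            mm.segment_lesion(np.full((50, 50, 3), 128, dtype=np.uint8))

    def test_holes_filled(self):
        img = np.full((60, 60), 200, dtype=np.uint8)
        img[15:45, 15:45] = 60
        img[28:32, 28:32] = 200          # hole
        lesion = mm.segment_lesion(np.dstack([img] * 3))
        assert lesion.mask[30, 30]


def _asymmetry_oracle(mask, gray):
    """Quadratic-loop transcription of the reflection-and-sum score."""
    pts = np.argwhere(mask).astype(float)
    c = pts.mean(axis=0)
    d = pts - c
    cov = d.T @ d / len(d)
    _, vecs = np.linalg.eigh(cov)
    f = np.where(mask, gray, 0.0)
    h, w = mask.shape
    scores = []
    for axis in vecs.T:
        total = 0.0
        for (r, col) in pts:
            dr, dc = r - c[0], col - c[1]
            proj = dr * axis[0] + dc * axis[1]
            mr = c[0] + 2 * proj * axis[0] - dr
            mc = c[1] + 2 * proj * axis[1] - dc
            ir, ic = int(round(mr)), int(round(mc))
            fm = f[ir, ic] if (0 <= ir < h and 0 <= ic < w) else 0.0
            total += abs(f[int(r), int(col)] - fm)
        scores.append(0.5 * total / len(pts))
    return float(np.mean(scores))


class TestAsymmetry:
    def test_matches_bruteforce_on_small_mask(self):
        mask = np.zeros((7, 7), bool)
        mask[2:5, 1:6] = True
        mask[1, 3] = True
        rng = np.random.default_rng(0)
        gray = rng.random((7, 7))
        img = (np.dstack([gray] * 3) * 255).astype(np.uint8)
        lesion = mm.mask_properties(mask)
        ours = mm.asymmetry_index(lesion, img)
        from skimage.color import rgb2gray
        oracle = _asymmetry_oracle(mask, rgb2gray(img))
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_doubly_symmetric_shapes_score_zero(self):
        for mask in (rasterize_disk(20, 64), rasterize_ellipse(12, 22, 64)):
            lesion = mm.mask_properties(mask)
            assert mm.asymmetry_index(lesion, flat_rgb(mask)) == pytest.approx(0.0, abs=1e-12)

    def test_half_disk_more_asymmetric_than_disk(self):
        disk = rasterize_disk(24, 80)
        yy = np.mgrid[:80, :80][0]
        half = disk & (yy <= 40)
        ai_disk = mm.asymmetry_index(mm.mask_properties(disk), flat_rgb(disk))
        ai_half = mm.asymmetry_index(mm.mask_properties(half), flat_rgb(half))
        assert ai_half > ai_disk

    def test_rotation_invariance_90_degrees(self):
        mask = _random_blob_mask(3)
        spec = LesionSpec(base_radius=13, irregularity_level=0.3,
                          image_size=(64, 64), n_colors=2)
        img = render_lesion_image(mask, spec, 3).pixels
        ai = mm.asymmetry_index(mm.mask_properties(mask), img)
        rot_mask = np.rot90(mask).copy()
        rot_img = np.rot90(img).copy()
        ai_rot = mm.asymmetry_index(mm.mask_properties(rot_mask), rot_img)
        assert ai_rot == pytest.approx(ai, abs=0.02)

    def test_misaligned_image_rejected(self):
        mask = rasterize_disk(10, 40)
        with pytest.raises(ValueError, match="match"):
            mm.asymmetry_index(mm.mask_properties(mask),
                               np.zeros((50, 50, 3), np.uint8))


class TestBorder:
    def test_convex_square_scores_one(self):
        sq = np.zeros((60, 60), bool)
        sq[10:50, 10:50] = True
        b = mm.border_irregularity(mm.mask_properties(sq), "convexity")
        assert b == pytest.approx(1.0, abs=1e-9)

    def test_disk_compactness_near_one(self):
        disk = rasterize_disk(100, 256)
        b = mm.border_irregularity(mm.mask_properties(disk), "compactness")
        assert b == pytest.approx(1.0, abs=0.02)

    def test_star_rougher_than_disk(self):
        n = 200
        yy, xx = np.mgrid[:n, :n]
        theta = np.arctan2(yy - n // 2, xx - n // 2)
        r = np.hypot(yy - n // 2, xx - n // 2)
        star = r <= 55 * (1 + 0.45 * np.cos(8 * theta))
        disk = rasterize_disk(np.sqrt(star.sum() / np.pi), n)
        b_star = mm.border_irregularity(mm.mask_properties(star))
        b_disk = mm.border_irregularity(mm.mask_properties(disk))
        assert b_star > b_disk

    def test_degenerate_mask_rejected(self):
        tiny = np.zeros((10, 10), bool)
        tiny[5, 5] = True
        with pytest.raises(ValueError):
            mm.border_irregularity(mm.mask_properties(tiny))


class TestColor:
    def test_two_point_distribution(self):
        mask = np.zeros((10, 10), bool)
        mask[2:4, :] = True            # 20 px
        img = np.zeros((10, 10, 3), np.uint8)
        img[2, :, :] = 0
        img[3, :, :] = 255
        c = mm.color_variation(img, mm.mask_properties(mask))
        assert c == pytest.approx(127.5)

    def test_matches_two_pass_variance_oracle(self):
        rng = np.random.default_rng(5)
        mask = rasterize_disk(15, 48)
        img = rng.integers(0, 255, (48, 48, 3)).astype(np.uint8)
        lesion = mm.mask_properties(mask)
        ours = mm.color_variation(img, lesion)
        stds = []
        for ch in range(3):
            vals = img[:, :, ch][mask].astype(float)
            mu = vals.sum() / len(vals)
            stds.append(np.sqrt(((vals - mu) ** 2).sum() / len(vals)))
        assert ours == pytest.approx(np.mean(stds), abs=1e-10)


class TestShape:
    def test_diameter_from_area_algebra(self):
        mask = rasterize_disk(50, 128)
        lesion = mm.mask_properties(mask)
        d, _ = mm.shape_scores(lesion)
        assert d == pytest.approx(np.sqrt(4 * lesion.area_AL / np.pi), rel=1e-12)
        assert d == pytest.approx(100.0, rel=0.01)

    def test_disk_roundness_close_to_one(self):
        lesion = mm.mask_properties(rasterize_disk(100, 256))
        assert mm.shape_scores(lesion)[1] == pytest.approx(1.0, abs=0.01)

    def test_ellipse_less_round_than_disk(self):
        ell = rasterize_ellipse(15, 60, 160)
        area = ell.sum()
        disk = rasterize_disk(np.sqrt(area / np.pi), 160)
        r_ell = mm.shape_scores(mm.mask_properties(ell))[1]
        r_disk = mm.shape_scores(mm.mask_properties(disk))[1]
        assert r_ell < r_disk

    def test_roundness_error_shrinks_with_radius(self):
        errs = []
        for r in (25, 50, 100, 200):
            lesion = mm.mask_properties(rasterize_disk(r, 2 * r + 16))
            errs.append(abs(1.0 - mm.shape_scores(lesion)[1]))
        assert all(errs[i + 1] < errs[i] for i in range(len(errs) - 1))

    def test_diameter_depends_only_on_area(self):
        """Shapes of equal area share D regardless of perimeter."""
        sq = np.zeros((80, 80), bool)
        sq[10:50, 10:50] = True                     # 1600 px square
        bar = np.zeros((80, 80), bool)
        bar[20:40, 0:80] = True                     # 1600 px bar
        d_sq = mm.shape_scores(mm.mask_properties(sq))[0]
        d_bar = mm.shape_scores(mm.mask_properties(bar))[0]
        assert d_sq == pytest.approx(d_bar, rel=1e-12)


class TestIdentitiesAndComposition:
    def test_roundness_compactness_identity(self):
        """roundness^2 * (P^2/4piA) == 1 exactly, any mask."""
        for seed in range(50):
            lesion = mm.mask_properties(_random_blob_mask(seed))
            _, roundness = mm.shape_scores(lesion)
            b = mm.border_irregularity(lesion, "compactness")
            assert roundness ** 2 * b == pytest.approx(1.0, rel=1e-12)

    def test_feature_vector_composition_and_determinism(self):
        spec = LesionSpec(base_radius=16, irregularity_level=0.4,
                          n_colors=3, noise_sd=6.0, image_size=(64, 64))
        img = render_lesion_image(generate_lesion_mask(spec, 8), spec, 8).pixels
        f1 = mm.feature_vector(img)
        f2 = mm.feature_vector(img)
        assert np.array_equal(f1.as_vector(), f2.as_vector())
        lesion = mm.segment_lesion(img)
        assert f1.asymmetry_AI == mm.asymmetry_index(lesion, img)
        assert f1.border_B == mm.border_irregularity(lesion)
        assert f1.color_C == mm.color_variation(img, lesion)
        d, roundness = mm.shape_scores(lesion)
        assert (f1.diameter_D, f1.roundness) == (d, roundness)

    def test_all_exported_components_nonnegative(self):
        spec = LesionSpec(base_radius=14, irregularity_level=0.6,
                          asymmetry_level=0.3, n_colors=2, noise_sd=8.0,
                          image_size=(64, 64))
        for seed in range(100):
            img = render_lesion_image(
                generate_lesion_mask(spec, seed), spec, seed).pixels
            vec = mm.feature_vector(img).as_vector()
            assert np.all(vec >= 0) and np.all(np.isfinite(vec))

    def test_mm_calibration_flag(self):
        img = flat_rgb(rasterize_disk(20, 64))
        f = mm.feature_vector(img, mm_per_px=0.2)     # D ~ 40 px ~ 8 mm
        assert f.suspicious_diameter is True
        f2 = mm.feature_vector(img, mm_per_px=0.05)   # ~ 2 mm
        assert f2.suspicious_diameter is False
        assert mm.feature_vector(img).suspicious_diameter is None
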