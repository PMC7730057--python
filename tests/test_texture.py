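"""GLCM construction and statistics against hand enumeration and a brute-force oracle."""

import math

import numpy as np
import pytest
from skimage.feature import graycomatrix

from busfeat.texture import (
    GlcmParams,
    STATISTIC_NAMES,
    compute_glcm,
    glcm_statistics,
    quantize,
    texture_feature_set,
    texture_glcms,
)


def brute_force_statistics(p):
    """Independent plain-Python double-loop evaluation of all 20 statistics."""
    g = p.shape[0]
    px = [sum(p[i][j] for j in range(g)) for i in range(g)]
    py = [sum(p[i][j] for i in range(g)) for j in range(g)]
    mu_x = sum((i + 1) * px[i] for i in range(g))
    mu_y = sum((j + 1) * py[j] for j in range(g))
    sd_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(g)))
    sd_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(g)))
    p_sum = {k: 0.0 for k in range(2, 2 * g + 1)}
    p_diff = {k: 0.0 for k in range(g)}
    for i in range(g):
        for j in range(g):
            p_sum[i + j + 2] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]

    def ent(vals):
        return -sum(v * math.log(v) for v in vals if v > 0)

    out = {}
    out["autocorrelation"] = sum((i + 1) * (j + 1) * p[i][j] for i in range(g) for j in range(g))
    out["contrast"] = sum((i - j) ** 2 * p[i][j] for i in range(g) for j in range(g))
    out["correlation"] = (
        (out["autocorrelation"] - mu_x * mu_y) / (sd_x * sd_y) if sd_x > 0 and sd_y > 0 else 0.0
    )
    out["cluster_prominence"] = sum(
        (i + j + 2 - mu_x - mu_y) ** 4 * p[i][j] for i in range(g) for j in range(g)
    )
    out["cluster_shade"] = sum(
        (i + j + 2 - mu_x - mu_y) ** 3 * p[i][j] for i in range(g) for j in range(g)
    )
    out["dissimilarity"] = sum(abs(i - j) * p[i][j] for i in range(g) for j in range(g))
    out["energy"] = sum(p[i][j] ** 2 for i in range(g) for j in range(g))
    out["entropy"] = ent([p[i][j] for i in range(g) for j in range(g)])
    out["homogeneity"] = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(g) for j in range(g))
    out["maximum_probability"] = max(p[i][j] for i in range(g) for j in range(g))
    out["sum_of_squares"] = sum((i + 1 - mu_x) ** 2 * p[i][j] for i in range(g) for j in range(g))
    out["sum_average"] = sum(k * v for k, v in p_sum.items())
    out["sum_entropy"] = ent(p_sum.values())
    out["sum_variance"] = sum((k - out["sum_average"]) ** 2 * v for k, v in p_sum.items())
    mu_d = sum(k * v for k, v in p_diff.items())
    out["difference_variance"] = sum((k - mu_d) ** 2 * v for k, v in p_diff.items())
    out["difference_entropy"] = ent(p_diff.values())
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(
        p[i][j] * math.log(px[i] * py[j])
        for i in range(g)
        for j in range(g)
        if px[i] * py[j] > 0 and p[i][j] > 0
    )
    hxy2 = ent([px[i] * py[j] for i in range(g) for j in range(g)])
    out["imc1"] = (out["entropy"] - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    out["imc2"] = math.sqrt(max(1 - math.exp(-2 * (hxy2 - out["entropy"])), 0.0))
    out["inverse_difference_normalized"] = sum(
        p[i][j] / (1 + abs(i - j) / g) for i in range(g) for j in range(g)
    )
    out["inverse_difference_moment_normalized"] = sum(
        p[i][j] / (1 + (i - j) ** 2 / g**2) for i in range(g) for j in range(g)
    )
    return out


class TestQuantize:
    def test_constant_maps_to_zero(self):
        assert quantize(np.full((5, 5), 42.0), 8).max() == 0

    def test_full_8bit_range_two_levels(self):
        img = np.array([[0, 100, 127], [128, 200, 255]], dtype=float)
        q = quantize(img, 2)
        assert q.tolist() == [[0, 0, 0], [1, 1, 1]]

    def test_integer_full_range_identity(self):
        rng = np.random.default_rng(0)
        for g in (2, 5, 16):
            img = rng.integers(0, g, (12, 12)).astype(float)
            img.flat[0], img.flat[1] = 0, g - 1  # force full range
            assert np.array_equal(quantize(img, g), img.astype(int))


class TestGlcm:
    def test_constant_image_single_cell(self):
        g = compute_glcm(np.zeros((2, 2), dtype=int), 1, 0, gray_levels=2)
        assert g.matrix[0, 0] == 1.0 and g.matrix.sum() == 1.0

    def test_horizontal_pairs_hand_enumerated(self):
        img = np.array([[0, 1], [0, 1]])
        g = compute_glcm(img, 1, 0, gray_levels=2)
        assert np.allclose(g.matrix, [[0, 0.5], [0.5, 0]])

    def test_vertical_pairs_hand_enumerated(self):
        img = np.array([[0, 1], [0, 1]])
        g = compute_glcm(img, 1, 90, gray_levels=2)
        assert np.allclose(g.matrix, [[0.5, 0], [0, 0.5]])

    def test_symmetric_and_normalized(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 8, (20, 20))
        for angle in (0, 45, 90, 135):
            g = compute_glcm(img, 2, angle, gray_levels=8)
            assert np.allclose(g.matrix, g.matrix.T)
            assert abs(g.matrix.sum() - 1.0) < 1e-12

    def test_matches_skimage_counts(self):
        # skimage's angle convention mirrors the diagonal offsets, so 45
        # degrees here corresponds to 3*pi/4 there (and vice versa);
        # symmetrized matrices make the axis directions sign-free.
        rng = np.random.default_rng(4)
        img = rng.integers(0, 6, (15, 17))
        mapping = {0: 0.0, 45: 3 * np.pi / 4, 90: np.pi / 2, 135: np.pi / 4}
        # diagonal angles only at d=1: skimage rounds sin(angle)*d, so its
        # diagonal displacement at d>=2 is not the standard (d, d) offset
        for d in (1, 2, 3):
            for angle, sk_angle in mapping.items():
                if d > 1 and angle in (45, 135):
                    continue
                ours = compute_glcm(img, d, angle, gray_levels=6).matrix
                ref = graycomatrix(
                    img.astype(np.uint8), [d], [sk_angle], levels=6, symmetric=True, normed=True
                )[:, :, 0, 0]
                assert np.allclose(ours, ref), (d, angle)

    def test_offset_too_large_rejected(self):
        with pytest.raises(ValueError):
            compute_glcm(np.zeros((3, 3), dtype=int), 5, 0, gray_levels=2)


class TestStatistics:
    def test_degenerate_single_cell(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        s = glcm_statistics(p)
        assert s["energy"] == 1.0 and s["entropy"] == 0.0
        assert s["contrast"] == 0.0 and s["dissimilarity"] == 0.0
        assert s["maximum_probability"] == 1.0 and s["homogeneity"] == 1.0

    def test_uniform_glcm_closed_forms(self):
        g = 5
        p = np.full((g, g), 1.0 / g**2)
        s = glcm_statistics(p)
        assert np.isclose(s["energy"], 1.0 / g**2)
        assert np.isclose(s["entropy"], 2 * np.log(g))

    def test_contrast_of_hand_enumerated_glcm(self):
        p = np.array([[0, 0.5], [0.5, 0]])
        assert np.isclose(glcm_statistics(p)["contrast"], 1.0)

    def test_oracle_equivalence_on_random_glcms(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            g = int(rng.integers(2, 9))
            m = rng.uniform(0, 1, (g, g))
            m = m + m.T
            m /= m.sum()
            ours = glcm_statistics(m)
            ref = brute_force_statistics(m)
            for name in STATISTIC_NAMES:
                assert abs(ours[name] - ref[name]) < 1e-10, name

    def test_ranges_on_nondegenerate_glcms(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            m = rng.uniform(0, 1, (6, 6))
            m = m + m.T
            m /= m.sum()
            s = glcm_statistics(m)
            assert 0 < s["energy"] <= 1
            assert s["entropy"] >= 0
            assert -1 <= s["correlation"] <= 1


class TestFeatureSet:
    def test_default_recipe_is_40_glcms_800_features(self):
        rng = np.random.default_rng(5)
        roi = rng.uniform(0, 255, (60, 60))
        assert len(texture_glcms(roi)) == 40
        fs = texture_feature_set(roi)
        assert len(fs) == 800
        assert len(set(fs.names)) == 800

    def test_reduced_grid_counts(self):
        roi = np.random.default_rng(6).uniform(0, 255, (30, 30))
        fs = texture_feature_set(roi, GlcmParams(distances=(1,), angles=(0,)))
        assert len(fs) == 20

    def test_deterministic_and_ordered(self):
        roi = np.random.default_rng(8).uniform(0, 255, (40, 40))
        a = texture_feature_set(roi)
        b = texture_feature_set(roi)
        assert np.array_equal(a.values, b.values)
        assert a.names[0] == "texture:d1:a0:autocorrelation"
        assert a.names[-1] == "texture:d10:a135:inverse_difference_moment_normalized"
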