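"""Grey-level degradation, GLCM accumulation and texture statistics."""

import numpy as np
import pytest
from scipy.stats import spearmanr
from skimage.feature import graycomatrix, graycoprops

from leafgrade.edges import LeafImage
from leafgrade.errors import ParameterError, TextureError
from leafgrade.texture import (
    GLCM,
    INVALID,
    degrade_gray,
    glcm,
    normalize_glcm,
    texture_contrast,
    texture_energy,
    texture_entropy,
)


def gray_image(levels):
    """Build a LeafImage whose luminance equals ``levels * 8`` exactly."""
    g = (np.asarray(levels) * 8).astype(np.uint8)
    return LeafImage(pixels=np.stack([g, g, g], axis=-1))


def brute_force_glcm(levels, offset, mask=None, n_levels=32):
    """Definitional nested-loop oracle: count pairs (x,y),(x+DX,y+DY)."""
    dx, dy = offset
    h, w = levels.shape
    counts = np.zeros((n_levels, n_levels))
    for y in range(h):
        for x in range(w):
            x2, y2 = x + dx, y + dy
            if not (0 <= x2 < w and 0 <= y2 < h):
                continue
            if levels[y, x] == INVALID or levels[y2, x2] == INVALID:
                continue
            if mask is not None and not (mask[y, x] and mask[y2, x2]):
                continue
            counts[levels[y, x], levels[y2, x2]] += 1
    return counts


class TestDegradeGray:
    def test_endpoints_and_bin_boundary(self):
        px = np.zeros((1, 3, 3), np.uint8)
        px[0, 0] = 0
        px[0, 1] = 255
        px[0, 2] = 8
        levels = degrade_gray(LeafImage(pixels=px))
        assert levels[0, 0] == 0
        assert levels[0, 1] == 31
        assert levels[0, 2] == 1

    def test_histogram_matches_per_pixel_binning(self):
        rng = np.random.default_rng(2)
        px = rng.integers(0, 256, (24, 24, 3)).astype(np.uint8)
        image = LeafImage(pixels=px)
        levels = degrade_gray(image)
        lum = np.rint(px.astype(float) @ [0.299, 0.587, 0.114])
        expected = np.minimum(lum.astype(int) // 8, 31)
        assert np.array_equal(levels, expected)

    def test_masked_pixels_flagged_invalid(self):
        px = np.full((4, 4, 3), 100, np.uint8)
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        levels = degrade_gray(LeafImage(pixels=px), mask)
        assert levels[0, 0] != INVALID
        assert np.all(levels[1:, :] == INVALID)


class TestGlcm:
    def test_two_by_two_example(self):
        levels = np.array([[0, 0], [1, 1]])
        g = glcm(levels, offset=(1, 0))
        assert g.counts[0, 0] == 1 and g.counts[1, 1] == 1
        assert g.counts.sum() == 2

    def test_constant_grid(self):
        levels = np.full((5, 7), 9)
        g = glcm(levels, offset=(1, 0))
        assert g.counts[9, 9] == 5 * (7 - 1)
        assert g.counts.sum() == 5 * 6

    @pytest.mark.parametrize("offset", [(1, 0), (0, 1), (1, 1), (-1, 2)])
    def test_matches_brute_force(self, offset):
        rng = np.random.default_rng(6)
        levels = rng.integers(0, 32, (8, 8))
        mask = rng.random((8, 8)) < 0.8
        g = glcm(levels, offset=offset, mask=mask)
        assert np.array_equal(g.counts, brute_force_glcm(levels, offset, mask))

    def test_matches_skimage_graycomatrix(self):
        # independent cross-check: skimage with angle 0 equals offset (1, 0)
        rng = np.random.default_rng(7)
        levels = rng.integers(0, 32, (16, 16)).astype(np.uint8)
        ours = glcm(levels, offset=(1, 0)).counts
        theirs = graycomatrix(levels, [1], [0], levels=32,
                              symmetric=False, normed=False)[:, :, 0, 0]
        assert np.array_equal(ours, theirs)

    def test_transpose_covariance(self):
        rng = np.random.default_rng(9)
        levels = rng.integers(0, 32, (12, 10))
        fwd = glcm(levels, offset=(2, -1)).counts
        bwd = glcm(levels, offset=(-2, 1)).counts
        assert np.array_equal(bwd, fwd.T)

    def test_pair_conservation_on_random_masks(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            levels = rng.integers(0, 32, (8, 8))
            mask = rng.random((8, 8)) < rng.uniform(0.3, 1.0)
            dx, dy = (1, 0) if rng.random() < 0.5 else (0, 1)
            valid = mask[:, :-1] & mask[:, 1:] if dy == 0 \
                else mask[:-1, :] & mask[1:, :]
            n_pairs = int(valid.sum())
            if n_pairs == 0:
                with pytest.raises(TextureError):
                    glcm(levels, (dx, dy), mask)
                continue
            g = glcm(levels, (dx, dy), mask)
            assert g.counts.sum() == n_pairs

    def test_zero_offset_rejected(self):
        with pytest.raises(ParameterError):
            glcm(np.zeros((4, 4), int), offset=(0, 0))


class TestNormalize:
    def test_two_entry_matrix(self):
        counts = np.zeros((32, 32))
        counts[0, 0] = counts[1, 1] = 1
        g = normalize_glcm(GLCM(counts=counts, offset=(1, 0)))
        assert g.counts[0, 0] == 0.5 and g.counts[1, 1] == 0.5
        assert g.normalized

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        g = GLCM(counts=rng.integers(0, 9, (32, 32)), offset=(1, 0))
        once = normalize_glcm(g)
        twice = normalize_glcm(once)
        assert twice is once

    def test_sums_to_one(self):
        rng = np.random.default_rng(2)
        g = normalize_glcm(GLCM(counts=rng.integers(0, 9, (32, 32)),
                                offset=(1, 0)))
        assert g.counts.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(TextureError):
            normalize_glcm(GLCM(counts=np.zeros((32, 32)), offset=(1, 0)))


class TestStatistics:
    def test_degenerate_single_entry(self):
        counts = np.zeros((32, 32))
        counts[3, 4] = 1.0
        g = GLCM(counts=counts, offset=(1, 0), normalized=True)
        assert texture_energy(g) == 1.0
        assert texture_entropy(g) == 0.0
        assert texture_contrast(g) == 1.0  # (3-4)**2

    def test_uniform_matrix_closed_forms(self):
        g = GLCM(counts=np.full((32, 32), 1 / 1024), offset=(1, 0),
                 normalized=True)
        assert texture_energy(g) == pytest.approx(1 / 1024, abs=1e-15)
        assert texture_entropy(g) == pytest.approx(10.0, abs=1e-12)

    def test_two_entry_entropy_is_one_bit(self):
        counts = np.zeros((32, 32))
        counts[0, 0] = counts[5, 9] = 0.5
        g = GLCM(counts=counts, offset=(1, 0), normalized=True)
        assert texture_entropy(g) == pytest.approx(1.0, abs=1e-12)
        assert texture_entropy(g, as_printed=True) == pytest.approx(-1.0)

    def test_diagonal_contrast_zero(self):
        counts = np.diag(np.arange(32, dtype=float))
        g = normalize_glcm(GLCM(counts=counts, offset=(1, 0)))
        assert texture_contrast(g) == 0.0

    def test_statistics_match_weighted_sum_oracles(self):
        rng = np.random.default_rng(13)
        p = rng.random((32, 32))
        p /= p.sum()
        g = GLCM(counts=p, offset=(1, 0), normalized=True)
        assert texture_energy(g) == pytest.approx(
            sum(p[i, j] ** 2 for i in range(32) for j in range(32)),
            abs=1e-12)
        assert texture_contrast(g) == pytest.approx(
            sum((i - j) ** 2 * p[i, j]
                for i in range(32) for j in range(32)), abs=1e-9)
        assert texture_entropy(g) == pytest.approx(
            -sum(p[i, j] * np.log2(p[i, j])
                 for i in range(32) for j in range(32)), abs=1e-9)

    def test_matches_skimage_graycoprops(self):
        rng = np.random.default_rng(14)
        levels = rng.integers(0, 32, (20, 20)).astype(np.uint8)
        g = normalize_glcm(glcm(levels, offset=(1, 0)))
        sk = graycomatrix(levels, [1], [0], levels=32, symmetric=False,
                          normed=True)
        assert texture_energy(g) == pytest.approx(
            float(graycoprops(sk, "ASM")[0, 0]), rel=1e-10)
        assert texture_contrast(g) == pytest.approx(
            float(graycoprops(sk, "contrast")[0, 0]), rel=1e-10)

    def test_raw_dialect_scales_with_counts(self):
        counts = np.zeros((32, 32))
        counts[0, 1] = 3
        g = GLCM(counts=counts, offset=(1, 0))
        assert texture_energy(g, raw=True) == 9.0
        assert texture_energy(g) == 1.0

    def test_energy_bounds_and_entropy_antagonism(self):
        rng = np.random.default_rng(15)
        energies, entropies = [], []
        for _ in range(60):
            counts = rng.random((32, 32)) ** rng.uniform(1, 30)
            g = normalize_glcm(GLCM(counts=counts, offset=(1, 0)))
            e = texture_energy(g)
            assert 1 / 1024 <= e <= 1.0
            energies.append(e)
            entropies.append(texture_entropy(g))
        rho = spearmanr(energies, entropies).statistic
        assert rho < 0
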