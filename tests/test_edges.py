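"""Laplacian-of-Gaussian kernel, smoothing, segmentation and contours."""

import math

import numpy as np
import pytest
from scipy import ndimage

from conftest import disk_mask, render_mask
from leafgrade.edges import (
    Contour,
    EdgeConfig,
    LeafImage,
    binarize,
    edge_map,
    extract_contour,
    gaussian_smooth,
    log_kernel,
    trace_boundary,
)
from leafgrade.errors import (
    AmbiguityError,
    ContourError,
    DetectionError,
    ParameterError,
)


def log_value(x, y, sigma):
    """Closed-form LoG used as the oracle for single grid points."""
    rho2 = x * x + y * y
    return (-1.0 / (math.pi * sigma**4) * (1 - rho2 / (2 * sigma**2))
            * math.exp(-rho2 / (2 * sigma**2)))


class TestLogKernel:
    def test_origin_value_sigma_one(self):
        k = log_kernel(EdgeConfig(sigma=1.0, kernel_radius=4))
        assert k[4, 4] == pytest.approx(-1.0 / math.pi, abs=1e-12)

    def test_zero_on_the_sqrt2_sigma_circle(self):
        # sigma = sqrt(2): the zero circle has radius 2, hitting grid points
        sigma = math.sqrt(2.0)
        k = log_kernel(EdgeConfig(sigma=sigma, kernel_radius=6))
        c = 6
        assert k[c, c + 2] == pytest.approx(0.0, abs=1e-15)
        assert k[c + 2, c] == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("sigma", [1.0, 1.7, 2.0, 3.3])
    def test_radial_symmetry_exact(self, sigma):
        k = log_kernel(EdgeConfig(sigma=sigma))
        assert np.array_equal(k, k[::-1, :])
        assert np.array_equal(k, k[:, ::-1])
        assert np.array_equal(k, k.T)

    @pytest.mark.parametrize("sigma", [1.0, 1.5, 2.0, 2.5])
    def test_sign_change_at_sqrt2_sigma_along_axis(self, sigma):
        k = log_kernel(EdgeConfig(sigma=sigma, kernel_radius=8))
        c = 8
        lo = math.floor(math.sqrt(2) * sigma)
        hi = math.ceil(math.sqrt(2) * sigma)
        assert k[c, c + lo] < 0 < k[c, c + hi]

    def test_matches_finite_difference_laplacian_of_gaussian(self):
        # densely sample the 2-D Gaussian and apply a 5-point FD Laplacian
        sigma, r, h = 1.0, 4, 0.01
        k = log_kernel(EdgeConfig(sigma=sigma, kernel_radius=r))
        worst = 0.0
        for x in range(-r, r + 1):
            for y in range(-r, r + 1):
                def g(a, b):
                    return (1 / (2 * math.pi * sigma**2)
                            * math.exp(-(a * a + b * b) / (2 * sigma**2)))
                lap = (g(x + h, y) + g(x - h, y) + g(x, y + h) + g(x, y - h)
                       - 4 * g(x, y)) / (h * h)
                worst = max(worst, abs(lap - k[y + r, x + r]))
        assert worst < 5e-3

    def test_truncated_sum_accounts_for_the_tail(self):
        # the sum over the truncated grid must equal the (near-zero) full
        # discrete sum minus the tail beyond the truncation radius
        cfg = EdgeConfig(sigma=2.0)  # radius 8 = 4 sigma
        k = log_kernel(cfg)
        big = log_kernel(EdgeConfig(sigma=2.0, kernel_radius=20))
        r = cfg.kernel_radius
        inner = big[20 - r:20 + r + 1, 20 - r:20 + r + 1]
        assert abs(k.sum() - inner.sum()) < 1e-12
        tail = big.sum() - inner.sum()
        assert abs(k.sum() - (big.sum() - tail)) < 1e-6
        assert abs(k.sum()) < 1e-3  # near zero for r >= 4 sigma

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ParameterError):
            EdgeConfig(sigma=0.0)
        with pytest.raises(ParameterError):
            EdgeConfig(sigma=-1.0)


class TestGaussianSmooth:
    def test_constant_grid_is_unchanged(self):
        out = gaussian_smooth(np.full((20, 20), 100.0), EdgeConfig(sigma=2.0))
        assert np.allclose(out, 100.0, atol=1e-9)

    def test_impulse_response_is_the_normalised_kernel(self):
        cfg = EdgeConfig(sigma=1.5, kernel_radius=5)
        grid = np.zeros((21, 21))
        grid[10, 10] = 1.0
        out = gaussian_smooth(grid, cfg)
        ax = np.arange(-5, 6, dtype=float)
        xx, yy = np.meshgrid(ax, ax)
        k = np.exp(-(xx**2 + yy**2) / (2 * 1.5**2))
        k /= k.sum()
        assert np.allclose(out[5:16, 5:16], k, atol=1e-12)

    def test_matches_nested_loop_convolution(self):
        cfg = EdgeConfig(sigma=1.0, kernel_radius=3)
        rng = np.random.default_rng(5)
        grid = rng.uniform(0, 255, (16, 16))
        # brute-force convolution with mirror-symmetric extension
        r = 3
        padded = np.pad(grid, r, mode="reflect")  # ndimage's "mirror"
        ax = np.arange(-r, r + 1, dtype=float)
        xx, yy = np.meshgrid(ax, ax)
        k = np.exp(-(xx**2 + yy**2) / 2.0)
        k /= k.sum()
        expected = np.empty_like(grid)
        for i in range(16):
            for j in range(16):
                acc = 0.0
                for a in range(-r, r + 1):
                    for b in range(-r, r + 1):
                        acc += k[a + r, b + r] * padded[i - a + r, j - b + r]
                expected[i, j] = acc
        assert np.allclose(gaussian_smooth(grid, cfg), expected, atol=1e-9)


class TestBinarize:
    def test_recovers_generator_area(self, small_leaf_solid):
        image, truth = small_leaf_solid
        mask = binarize(image)
        assert abs(mask.sum() - truth.true_area_px) <= 0.02 * truth.true_area_px

    def test_all_background_raises(self):
        px = np.full((64, 64, 3), 250, np.uint8)
        with pytest.raises(DetectionError):
            binarize(LeafImage(pixels=px))

    def test_idempotent_on_mask_rendering(self, small_leaf_solid):
        image, _ = small_leaf_solid
        mask = binarize(image)
        again = binarize(render_mask(mask))
        assert np.array_equal(mask, again)

    def test_keeps_only_largest_component(self):
        mask = disk_mask((256, 256), (128, 128), 60)
        mask |= disk_mask((256, 256), (30, 30), 5)  # a speck
        out = binarize(render_mask(mask))
        assert out.sum() == disk_mask((256, 256), (128, 128), 60).sum()


class TestContour:
    def test_disk_contour_length_near_circumference(self):
        image = render_mask(disk_mask((512, 512), (256, 256), 100))
        contour = extract_contour(image)
        assert contour.length() == pytest.approx(2 * math.pi * 100, rel=0.05)

    def test_contour_is_closed_eight_connected_simple(self, small_leaf):
        image, _ = small_leaf
        contour = extract_contour(image)
        assert contour.closed
        assert contour.is_eight_connected()
        assert not contour.has_duplicates()

    def test_square_contour_encloses_area(self):
        mask = np.zeros((512, 512), bool)
        mask[100:300, 150:350] = True
        contour = extract_contour(render_mask(mask))
        pts = contour.points.astype(float)
        y, x = pts[:, 0], pts[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
        assert area == pytest.approx(200 * 200, rel=0.02)

    def test_blank_image_raises_contour_error(self):
        px = np.full((64, 64, 3), 250, np.uint8)
        with pytest.raises(ContourError):
            extract_contour(LeafImage(pixels=px))

    def test_two_similar_objects_are_ambiguous(self):
        mask = disk_mask((512, 512), (150, 150), 70)
        mask |= disk_mask((512, 512), (360, 360), 68)
        with pytest.raises(AmbiguityError):
            extract_contour(render_mask(mask))

    def test_component_count_never_grows_with_sigma(self):
        # a disk with three holes of very different sizes
        mask = disk_mask((512, 512), (256, 256), 150)
        for cy, cx, r in ((200, 200, 2), (250, 300, 5), (320, 230, 12)):
            mask &= ~disk_mask((512, 512), (cy, cx), r)
        image = render_mask(mask)
        counts = []
        for sigma in (1.0, 1.5, 2.0, 3.0, 4.0, 6.0):
            zc = edge_map(image, EdgeConfig(sigma=sigma))
            _, n = ndimage.label(zc, np.ones((3, 3), int))
            counts.append(n)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_trace_boundary_rejects_empty_mask(self):
        with pytest.raises(ContourError):
            trace_boundary(np.zeros((10, 10), bool))

    def test_orientation_is_positive_shoelace(self, small_leaf):
        image, _ = small_leaf
        pts = extract_contour(image).points.astype(float)
        y, x = pts[:, 0], pts[:, 1]
        assert np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y) > 0
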