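"""Isotropic and anisotropic KDE against direct reference implementations."""

import numpy as np
import pytest

from densestorm.density_estimation import (
    KernelWindow,
    anisotropic_kde,
    anisotropic_kernel,
    gaussian_kde,
    local_covariance,
)
from densestorm.localization_io import render_histogram


from tests_reference import brute_force_anisotropic, brute_force_gaussian


class TestGaussianKDE:
    def test_sigma_zero_is_identity(self, rng):
        img = rng.poisson(1.0, (32, 32)).astype(float)
        np.testing.assert_array_equal(gaussian_kde(img, 0.0).values, img)

    def test_delta_response_unit_mass(self):
        img = np.zeros((64, 64))
        img[32, 32] = 1.0
        out = gaussian_kde(img, 2.0).values
        assert abs(out.sum() - 1.0) < 1e-6

    def test_matches_bruteforce_convolution(self, rng):
        img = rng.poisson(0.3, (64, 64)).astype(float)
        fast = gaussian_kde(img, 2.0).values
        slow = brute_force_gaussian(img, 2.0)
        np.testing.assert_allclose(fast, slow, atol=1e-8)


class TestLocalCovariance:
    def test_rotationally_symmetric_window_gives_equal_eigenvalues(self):
        win = KernelWindow(size=9, epsilon=0.0)
        img = np.zeros((21, 21))
        rr, cc = np.mgrid[:21, :21]
        img += np.exp(-((rr - 10.0) ** 2 + (cc - 10.0) ** 2) / 8.0)
        cov = local_covariance(img, win, (10, 10))
        lam = cov.eigenvalues
        assert abs(lam[0] - lam[1]) < 1e-9

    def test_single_row_is_rank_deficient_before_regularization(self):
        win = KernelWindow(size=7, epsilon=0.0)
        img = np.zeros((15, 15))
        img[7, :] = 1.0
        cov = local_covariance(img, win, (7, 7))
        lam = np.sort(cov.eigenvalues)
        assert lam[0] == pytest.approx(0.0, abs=1e-12)
        # principal axis along the row (column direction)
        _, vecs = np.linalg.eigh(cov.sigma)
        principal = vecs[:, -1]
        assert abs(abs(principal[1]) - 1.0) < 1e-9

    def test_matches_direct_weighted_moments(self, rng):
        win = KernelWindow(size=11, epsilon=0.0)
        patch = rng.random((11, 11))
        img = np.zeros((31, 31))
        img[10:21, 10:21] = patch
        cov = local_covariance(img, win, (15, 15))
        w = patch.ravel()
        d = win.offsets
        mu = (w[:, None] * d).sum(0) / w.sum()
        ref = np.einsum("n,ni,nj->ij", w, d - mu, d - mu) / w.sum()
        np.testing.assert_allclose(cov.sigma, ref, atol=1e-10)

    def test_all_zero_window_flagged_degenerate(self):
        win = KernelWindow(size=5)
        cov = local_covariance(np.zeros((11, 11)), win, (5, 5))
        assert cov.degenerate


class TestAnisotropicKernel:
    def test_isotropic_covariance_reduces_to_gaussian(self):
        win = KernelWindow(size=11, scale=1.0)
        kernel = anisotropic_kernel(np.eye(2) * 3.0, win)
        ax = np.arange(11) - 5
        g = np.exp(-(ax**2) / (2 * 3.0))
        ref = np.outer(g, g)
        ref /= ref.sum()
        np.testing.assert_allclose(kernel, ref, atol=1e-10)

    def test_elongation_matches_eigenvalue_ratio(self):
        lam1, lam2 = 6.0, 1.5
        win = KernelWindow(size=21, scale=1.0)
        kernel = anisotropic_kernel(np.diag([lam2, lam1]), win)
        d = np.arange(21) - 10
        sd_col = np.sqrt((kernel.sum(0) * d**2).sum())
        sd_row = np.sqrt((kernel.sum(1) * d**2).sum())
        assert sd_col / sd_row == pytest.approx(np.sqrt(lam1 / lam2), rel=0.02)

    def test_unit_sum_and_point_symmetry(self, rng):
        a = rng.random((2, 2))
        sigma = a @ a.T + 0.5 * np.eye(2)
        kernel = anisotropic_kernel(sigma, KernelWindow(size=9, scale=2.0))
        assert abs(kernel.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(kernel, kernel[::-1, ::-1], atol=1e-14)

    def test_singular_covariance_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            anisotropic_kernel(np.zeros((2, 2)), KernelWindow(size=5, epsilon=0.0))


class TestAnisotropicKDE:
    def test_zero_image_maps_to_zero(self):
        out = anisotropic_kde(np.zeros((32, 32)), KernelWindow(size=7))
        assert np.all(out.values == 0)

    def test_matches_bruteforce_reference(self, rng):
        img = rng.poisson(0.4, (64, 64)).astype(float)
        win = KernelWindow(size=7, scale=1.5)
        fast = anisotropic_kde(img, win).values
        slow = brute_force_anisotropic(img, win)
        np.testing.assert_allclose(fast, slow, atol=1e-8)

    @pytest.mark.parametrize("method", ["gaussian", "anisotropic"])
    def test_mass_conservation_away_from_borders(self, rng, method):
        win = KernelWindow(size=11, scale=1.0)
        img = np.zeros((64, 64))
        img[16:48, 16:48] = rng.poisson(1.0, (32, 32))
        if method == "gaussian":
            out = gaussian_kde(img, 1.5).values
        else:
            out = anisotropic_kde(img, win).values
        assert abs(out.sum() - img.sum()) / img.sum() < 1e-6

    def test_90_degree_rotation_equivariance(self, filament_dataset):
        _, locs = filament_dataset
        hist = render_histogram(locs, 10.0, (0, 640, 0, 640))
        img = hist.counts.astype(float)
        win = KernelWindow(size=7, scale=1.5)
        rotated_first = anisotropic_kde(np.rot90(img), win).values
        rotated_after = np.rot90(anisotropic_kde(img, win).values)
        np.testing.assert_allclose(rotated_first, rotated_after, atol=1e-10)

    def test_isotropy_limit_close_to_gaussian_kde(self, rng):
        # statistically isotropic point field: adaptive kernels stay round,
        # so the two estimators agree at matched second moments
        img = rng.poisson(5.0, (96, 96)).astype(float)
        win = KernelWindow(size=11, scale=1.0)
        aniso = anisotropic_kde(img, win).values
        # matched bandwidth: mean per-pixel covariance eigenvalue
        from densestorm.density_estimation import local_covariance_field

        sigma_field, _ = local_covariance_field(img, win)
        occupied = img > 0
        mean_var = float(np.mean(np.trace(sigma_field[occupied], axis1=1, axis2=2) / 2))
        iso = gaussian_kde(img, np.sqrt(mean_var)).values
        assert np.abs(aniso - iso).sum() / img.sum() < 0.05

    def test_edge_sharper_than_matched_isotropic(self):
        # straight vertical filament: cross-profile of the adaptive estimate
        # is narrower than an isotropic blur of matched along-axis smoothing
        img = np.zeros((64, 64))
        img[8:56, 31] = 5.0
        win = KernelWindow(size=11, scale=2.0)
        aniso = anisotropic_kde(img, win).values
        from densestorm.density_estimation import local_covariance_field

        sigma_field, _ = local_covariance_field(img, win)
        lam_max = np.linalg.eigvalsh(sigma_field[30, 31]).max()
        iso = gaussian_kde(img, win.scale * np.sqrt(lam_max)).values

        def fwhm(profile):
            profile = profile / profile.max()
            above = np.nonzero(profile >= 0.5)[0]
            return above[-1] - above[0] + 1

        assert fwhm(aniso[32]) < fwhm(iso[32])
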