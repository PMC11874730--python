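"""NUFFT operators, coil simulation/estimation, CG-SENSE."""

import numpy as np
import pytest

from spiralcine.encoding import (CoilSensitivities, KSpaceBundle, NufftOperator,
                                 ShapeError, cg_sense, estimate_coils_adaptive,
                                 nufft_adjoint, nufft_forward, simulate_coils)
from spiralcine.phantom import PhantomConfig, render_frame
from spiralcine.function_metrics import nrmse
from spiralcine.trajectory import SpiralTrajectory, design_spiral


def brute_force_dft(image, pts):
    """Independent non-uniform DFT sum oracle."""
    n = image.shape[0]
    c = np.arange(n) - n // 2
    out = np.empty(len(pts), dtype=complex)
    for i, (ky, kx) in enumerate(pts):
        phase = np.exp(-2j * np.pi * (ky * c[:, None] + kx * c[None, :]))
        out[i] = np.sum(image * phase)
    return out


from tests_support import cartesian_traj  # noqa: E402


@pytest.fixture(scope="module")
def rand_image16():
    rng = np.random.default_rng(7)
    return rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))


class TestNufft:
    def test_forward_matches_brute_force_dft(self, small_traj, rand_image16):
        pts = small_traj.flat_coords()
        oracle = brute_force_dft(rand_image16, pts)
        for mode, tol in [("gridding", 1e-5), ("exact", 1e-12)]:
            op = NufftOperator(small_traj, 16, mode=mode)
            y = op.forward(rand_image16)
            assert np.linalg.norm(y - oracle) / np.linalg.norm(oracle) <= tol

    def test_dc_sample_equals_pixel_sum(self, small_traj):
        img = np.full((16, 16), 0.7 + 0.1j)
        coils = simulate_coils(16, 1, smoothness=np.inf)
        bundle = nufft_forward(img, coils, small_traj, mode="exact")
        # every arm starts at k = 0
        assert np.allclose(bundle.samples[:, 0, 0], img.sum(), rtol=1e-9)

    def test_centered_point_source_flat_magnitude(self, small_traj):
        img = np.zeros((16, 16), complex)
        img[8, 8] = 3.0
        op = NufftOperator(small_traj, 16, mode="exact")
        y = op.forward(img)
        assert np.allclose(np.abs(y), 3.0)

    def test_adjointness(self, small_traj):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        y = rng.normal(size=5 * 40) + 1j * rng.normal(size=5 * 40)
        for mode, tol in [("gridding", 1e-3), ("exact", 1e-10)]:
            op = NufftOperator(small_traj, 16, mode=mode)
            ax = op.forward(x)
            aty = op.adjoint(y)
            err = abs(np.vdot(y, ax) - np.vdot(aty, x))
            assert err / (np.linalg.norm(ax) * np.linalg.norm(y)) <= tol

    def test_zero_kspace_zero_image(self, small_traj):
        coils = simulate_coils(16, 2, seed=1)
        z = KSpaceBundle(np.zeros((5, 40, 2)), np.arange(5) * 1e-3, small_traj)
        img = nufft_adjoint(z, coils)
        assert np.all(img == 0)

    def test_dense_spiral_gridding_recovers_phantom(self):
        """Fully sampled (R=1) spiral: density-compensated adjoint recovers
        the object to NRMSE <= 0.05."""
        traj = design_spiral(fov_mm=32.0, resolution_mm=1.0, n_arms=16,
                             center_undersampling=0.5, edge_undersampling=0.5,
                             n_samples=512, matrix=32)
        cfg = PhantomConfig(grid=32, pixel_mm=8.0)
        truth = render_frame(cfg, 0.0).image
        coils = simulate_coils(32, 1, smoothness=np.inf)
        bundle = nufft_forward(truth, coils, traj)
        img = nufft_adjoint(bundle, coils, use_dcf=True)
        scale = np.vdot(img, truth).real / np.vdot(img, img).real
        assert nrmse(scale * np.abs(img), np.abs(truth)) <= 0.05

    def test_grid_mismatch_raises(self, small_traj):
        coils = simulate_coils(16, 2)
        with pytest.raises(ShapeError):
            nufft_forward(np.zeros((8, 8)), coils, small_traj)


class TestCoils:
    def test_reproducible_per_seed(self):
        a = simulate_coils(32, 4, seed=5)
        b = simulate_coils(32, 4, seed=5)
        assert np.array_equal(a.maps, b.maps)
        c = simulate_coils(32, 4, seed=6)
        assert not np.array_equal(a.maps, c.maps)

    def test_infinite_smoothness_constant_map(self):
        coils = simulate_coils(16, 1, smoothness=np.inf)
        assert np.all(coils.maps == coils.maps[0, 0, 0])

    def test_smoothness_total_variation_bound(self):
        """Finite-difference oracle: per-coil TV stays below a bound that a
        random rough map would violate by orders of magnitude."""
        coils = simulate_coils(64, 8, seed=2)
        for m in coils.maps:
            tv = (np.abs(np.diff(m, axis=0)).sum() +
                  np.abs(np.diff(m, axis=1)).sum())
            # a white-noise map scores ~2.8 on this ratio
            assert tv / np.abs(m).sum() < 0.15

    def test_rss_positive(self):
        coils = simulate_coils(48, 6, seed=9)
        assert coils.rss().min() > 0


class TestAdaptiveEstimation:
    def test_single_uniform_coil(self):
        imgs = np.full((1, 16, 16), 2.0 + 0.0j)
        est = estimate_coils_adaptive(imgs)
        assert np.allclose(np.abs(est.maps), 1.0, atol=1e-6)

    def test_recovers_simulated_maps(self):
        coils = simulate_coils(32, 4, seed=4)
        img = np.ones((32, 32))          # uniform object
        coil_images = coils.maps * img
        est = estimate_coils_adaptive(coil_images, block_size=4)
        truth_mag = np.abs(coils.maps) / coils.rss()
        err = np.abs(np.abs(est.maps) - truth_mag)
        assert err.max() <= 0.02

    def test_subsampled_estimate_close_to_full(self):
        coils = simulate_coils(64, 4, seed=8)
        coil_images = coils.maps * np.ones((64, 64))
        full = estimate_coils_adaptive(coil_images)
        sub = estimate_coils_adaptive(coil_images, subsample_factor=4)
        err = np.abs(np.abs(full.maps) - np.abs(sub.maps))
        assert err.mean() <= 0.05

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            estimate_coils_adaptive(np.zeros((2, 8, 8), complex))


class TestCgSense:
    def test_cartesian_single_coil_matches_inverse_dft(self, rand_image16):
        traj = cartesian_traj(16)
        coils = simulate_coils(16, 1, smoothness=np.inf)
        op = NufftOperator(traj, 16, mode="exact")
        y = op.forward(rand_image16).reshape(16, 16)
        # independent oracle: inverse FFT of the sample grid
        oracle = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(y)))
        bundle = KSpaceBundle(y.reshape(16, 16, 1).reshape(16, 16, 1),
                              np.arange(16) * 1e-3, traj)
        x = cg_sense(bundle, traj, coils, n_iter=10, mode="exact")
        rel = np.linalg.norm(x - oracle) / np.linalg.norm(oracle)
        assert rel <= 1e-3
        assert np.allclose(oracle, rand_image16, atol=1e-10)

    def test_residual_nonincreasing(self, desk_traj, desk_config):
        truth = render_frame(desk_config, 0.0).image
        coils = simulate_coils(64, 4, seed=1)
        bundle = nufft_forward(truth, coils, desk_traj)
        _, res = cg_sense(bundle, desk_traj, coils, n_iter=8,
                          return_residuals=True)
        assert np.all(res[1:] <= 1.01 * res[:-1])

    def test_beats_gridding_on_undersampled_phantom(self, desk_traj, desk_config):
        truth = render_frame(desk_config, 0.0).image
        coils = simulate_coils(64, 8, seed=5)
        bundle = nufft_forward(truth, coils, desk_traj)
        grid_img = nufft_adjoint(bundle, coils, use_dcf=True)
        cg_img = cg_sense(bundle, desk_traj, coils, n_iter=10)
        s_g = np.vdot(grid_img, truth).real / np.vdot(grid_img, grid_img).real
        e_grid = nrmse(np.abs(s_g * grid_img), np.abs(truth))
        e_cg = nrmse(np.abs(cg_img), np.abs(truth))
        assert e_cg < e_grid

    def test_overdetermined_noiseless_recovery(self):
        """Dense sampling + many iterations: NRMSE <= 0.02."""
        traj = design_spiral(fov_mm=32.0, resolution_mm=1.0, n_arms=24,
                             center_undersampling=0.4, edge_undersampling=0.6,
                             n_samples=384, matrix=32)
        cfg = PhantomConfig(grid=32, pixel_mm=8.0)
        truth = render_frame(cfg, 0.2).image
        coils = simulate_coils(32, 4, seed=2)
        bundle = nufft_forward(truth, coils, traj)
        x = cg_sense(bundle, traj, coils, n_iter=30)
        assert nrmse(np.abs(x), np.abs(truth)) <= 0.02

    def test_bad_iteration_count(self, small_traj):
        coils = simulate_coils(16, 1)
        bundle = KSpaceBundle(np.zeros((5, 40, 1)), np.arange(5.0), small_traj)
        with pytest.raises(ValueError):
            cg_sense(bundle, small_traj, coils, n_iter=0)
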