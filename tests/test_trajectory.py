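"""Spiral design, rotation schedule, gradient chain, density weights."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spiralcine.trajectory import (GradientTransferFunction, ParameterError,
                                   SpiralTrajectory, apply_gstf,
                                   density_compensation, design_spiral,
                                   gradients_to_kspace, measure_undersampling,
                                   rotation_schedule, synthetic_gstf,
                                   triangular_rewinder)

TWO_PI = 2 * np.pi


def union_angles(offsets, n_arms):
    return np.sort(np.unique(np.concatenate(
        [np.mod(o + np.arange(n_arms) * TWO_PI / n_arms, TWO_PI)
         for o in offsets])))


def max_gap(angles):
    gaps = np.diff(np.concatenate([angles, [angles[0] + TWO_PI]]))
    return gaps.max()


class TestDesignSpiral:
    def test_default_geometry_undersampling_factors(self):
        """The 592 mm / 1.29 mm / 13-arm design is ~5x undersampled at the
        k-space center and ~15x at the edge."""
        traj = design_spiral(fov_mm=592.0, resolution_mm=1.29, n_arms=13)
        assert round(measure_undersampling(traj, 0.01)) == 5
        assert round(measure_undersampling(traj, 0.5)) == 15

    def test_kmax_is_half(self):
        traj = design_spiral(fov_mm=256.0, resolution_mm=2.0, n_arms=13,
                             n_samples=128, matrix=128)
        assert abs(traj.kmax - 0.5) < 1e-6

    def test_center_out(self, desk_traj):
        starts = np.hypot(desk_traj.arm_coords[:, 0, 0],
                          desk_traj.arm_coords[:, 0, 1])
        assert np.all(starts < 1e-6)

    def test_arms_are_rotated_copies(self, desk_traj):
        a = TWO_PI / desk_traj.n_arms
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        expected = desk_traj.arm_coords[0] @ rot.T
        assert np.abs(expected - desk_traj.arm_coords[1]).max() < 1e-9

    def test_undersampling_nondecreasing_in_radius(self):
        traj = design_spiral(fov_mm=592.0, resolution_mm=1.29, n_arms=13)
        radii = np.linspace(0.05, 0.5, 12)
        r_vals = [measure_undersampling(traj, r) for r in radii]
        assert np.all(np.diff(r_vals) > -0.05)

    @pytest.mark.parametrize("kwargs", [dict(fov_mm=-1), dict(resolution_mm=0),
                                        dict(n_arms=0)])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ParameterError):
            design_spiral(**{**dict(fov_mm=256.0, resolution_mm=2.0,
                                    n_arms=13, n_samples=64), **kwargs})


class TestRotationSchedule:
    def test_single_pattern(self):
        assert rotation_schedule(1, 13).tolist() == [0.0]

    def test_first_offsets_13_arms(self):
        # brute-force gap bisection gives pi/13 then pi/26 then 3*pi/26
        offs = rotation_schedule(4, 13)
        assert np.allclose(offs, [0, np.pi / 13, np.pi / 26, 3 * np.pi / 26])
        angles = union_angles(offs, 13)
        assert np.allclose(max_gap(angles), np.pi / 26)

    def test_each_offset_bisects_largest_gap(self):
        """Brute-force re-check of the bisection property."""
        offs = rotation_schedule(8, 13)
        for i in range(1, len(offs)):
            angles = union_angles(offs[:i], 13)
            gaps = np.diff(np.concatenate([angles, [angles[0] + TWO_PI]]))
            g = gaps.max()
            starts = angles[np.flatnonzero(gaps > g - 1e-12)]
            mid = (starts.min() + g / 2) % (TWO_PI / 13)
            assert abs(offs[i] - mid) < 1e-9

    def test_eight_patterns_cover_104_angles(self):
        offs = rotation_schedule(8, 13)
        angles = union_angles(offs, 13)
        assert angles.size == 104
        assert max_gap(angles) <= 2 * TWO_PI / 104 + 1e-12

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(n_arms=st.integers(3, 17), n_patterns=st.integers(1, 8))
    def test_schedule_gap_bound_property(self, n_arms, n_patterns):
        """Gap bisection always keeps the largest gap within twice the
        ideal uniform spacing, for any arm/pattern count."""
        offs = rotation_schedule(n_patterns, n_arms)
        angles = union_angles(offs, n_arms)
        assert angles.size == n_arms * n_patterns
        assert max_gap(angles) <= 2 * TWO_PI / angles.size + 1e-12


class TestGstf:
    def test_identity_response(self):
        g = np.sin(np.linspace(0, 20, 256))
        gstf = GradientTransferFunction(np.linspace(0, 1e6, 64),
                                        np.ones((1, 64)))
        out = apply_gstf(g, gstf, dt=1e-6)
        assert np.abs(out - g).max() < 1e-9

    def test_pure_delay_shifts_samples(self):
        dt = 1e-6
        n = 512
        f = np.fft.rfftfreq(n, dt)
        tau = 2 * dt
        gstf = GradientTransferFunction(f, np.exp(-2j * np.pi * f * tau)[None])
        g = np.exp(-0.5 * ((np.arange(n) - 200) / 12.0) ** 2)
        out = apply_gstf(g, gstf, dt)
        assert np.abs(out[2:] - g[:-2]).max() < 1e-6

    def test_halving_response(self):
        g = np.random.default_rng(0).normal(size=128)
        gstf = GradientTransferFunction(np.linspace(0, 1e6, 16),
                                        0.5 * np.ones((1, 16)))
        assert np.allclose(apply_gstf(g, gstf, 1e-6), 0.5 * g)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        gstf = synthetic_gstf()
        x, y = rng.normal(size=256), rng.normal(size=256)
        dt = 4.8e-6  # within the synthetic response's frequency support
        lhs = apply_gstf(2.5 * x - 1.2 * y, gstf, dt)
        rhs = 2.5 * apply_gstf(x, gstf, dt) - 1.2 * apply_gstf(y, gstf, dt)
        assert np.abs(lhs - rhs).max() < 1e-9

    def test_bandwidth_mismatch_warns(self):
        gstf = GradientTransferFunction(np.linspace(0, 1e3, 16),
                                        np.ones((1, 16)))
        with pytest.warns(UserWarning):
            apply_gstf(np.ones(64), gstf, dt=1e-6)

    def test_dc_gain_bound_enforced(self):
        with pytest.raises(ParameterError):
            GradientTransferFunction(np.linspace(0, 1e4, 8),
                                     1.5 * np.ones((1, 8)))


class TestGradientsToKspace:
    def test_constant_gradient_linear_k(self):
        k = gradients_to_kspace(np.ones(100), dt=1e-5, gyromagnetic_ratio=1.0)
        assert np.allclose(k, np.arange(100) * 1e-5, atol=1e-12)

    def test_zero_waveform(self):
        assert np.all(gradients_to_kspace(np.zeros((2, 50)), 1e-5) == 0)

    def test_rewinder_nulls_zeroth_moment(self):
        rng = np.random.default_rng(2)
        g = rng.normal(size=(2, 300))
        g_rw = triangular_rewinder(g, dt=1e-5)
        k = gradients_to_kspace(g_rw, dt=1e-5, gyromagnetic_ratio=1.0)
        assert np.abs(k[:, -1]).max() < 1e-6


class TestDensityCompensation:
    @staticmethod
    def radial_spokes(n_arms=12, n_samples=24):
        k = np.linspace(0, 0.5, n_samples)
        ang = 2 * np.pi * np.arange(n_arms) / n_arms
        arms = np.stack([np.outer(np.cos(ang), k), np.outer(np.sin(ang), k)],
                        axis=-1)
        return SpiralTrajectory(arm_coords=arms, n_arms=n_arms, dwell_time=1e-5,
                                rotation_offset=0.0, fov_mm=64.0,
                                resolution_mm=1.0)

    def test_radial_weights_proportional_to_radius(self):
        """Voronoi-cell-area oracle: interior weights of uniform radial
        spokes scale with |k|."""
        from scipy.spatial import Voronoi
        traj = self.radial_spokes()
        w = density_compensation(traj).reshape(12, 24)  # (n_arms, n_samples)
        k = np.hypot(*traj.arm_coords[0].T)
        # Voronoi oracle on the flat point set
        pts = traj.flat_coords()
        vor = Voronoi(pts)

        def cell_area(i):
            region = vor.regions[vor.point_region[i]]
            if -1 in region or len(region) == 0:
                return np.nan
            poly = vor.vertices[region]
            x, y = poly[:, 0], poly[:, 1]
            return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))

        interior = slice(3, 22)  # away from center and the open boundary
        areas = np.array([cell_area(i) for i in range(24)])[interior]
        w0 = w[0, interior]
        # oracle confirms the cell area is linear in |k|; the implementation
        # must match both the area and the |k| law to 5 %
        ratio_area = w0 / areas
        assert ratio_area.std() / ratio_area.mean() < 0.05
        ratio_k = w0 / k[interior]
        assert ratio_k.std() / ratio_k.mean() < 0.05

    def test_single_sample_weight_one(self):
        arms = np.zeros((1, 1, 2))
        traj = SpiralTrajectory(arms, 1, 1e-5, 0.0, 64.0, 1.0)
        assert density_compensation(traj).tolist() == [1.0]

    def test_all_weights_positive_for_default_design(self, desk_traj):
        w = density_compensation(desk_traj)
        assert np.all(w > 0)
        assert np.all(np.isfinite(w))
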