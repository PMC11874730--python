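"""Variable-density spiral trajectory design and gradient-chain utilities.

The real-time acquisition uses 13 center-out spiral interleaves per frame,
equally distributed over 2*pi, with an azimuthal undersampling factor of
about 5 at the k-space center rising to about 15 at the edge.  Successive
frame patterns are rotated so that each new pattern bisects the largest
angular gap left by all previous ones, which lets eight rotated patterns
tile k-space densely enough for a segmented (self-gated) reconstruction.

Conventions (package-wide): k-space coordinates are normalized to
[-0.5, 0.5) in units of cycles per reconstructed pixel, so ``|k| = 0.5``
corresponds to the stated spatial resolution.  Images are row-major with
the origin at the top-left.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import interp1d

GAMMA_PROTON = 42.577478518e6  # Hz/T, proton gyromagnetic ratio over 2*pi


class ParameterError(ValueError):
    """Invalid geometry or design parameter."""


@dataclass(frozen=True)
class SpiralTrajectory:
    """A set of rotated copies of one center-out spiral interleave.

    Attributes
    ----------
    arm_coords : ndarray, shape (n_arms, n_samples, 2)
        Normalized (kx, ky) per readout sample, in cycles/pixel,
        bounded by ``|k| <= 0.5``.
    n_arms : int
        Interleaves per pattern (13 for the default real-time frame).
    dwell_time : float
        Readout sample spacing in seconds.
    rotation_offset : float
        Global rotation of the whole pattern, radians.
    fov_mm, resolution_mm : float
        Reconstructed field of view and spatial resolution.
    """

    arm_coords: np.ndarray
    n_arms: int
    dwell_time: float
    rotation_offset: float
    fov_mm: float
    resolution_mm: float
    center_undersampling: float = 5.0
    edge_undersampling: float = 15.0

    @property
    def n_samples(self) -> int:
        return self.arm_coords.shape[1]

    @property
    def kmax(self) -> float:
        return float(np.max(np.hypot(self.arm_coords[..., 0], self.arm_coords[..., 1])))

    @property
    def fov_pixels(self) -> float:
        """FOV measured in resolution elements; sets the Nyquist spacing 1/N."""
        return self.fov_mm / self.resolution_mm

    def flat_coords(self) -> np.ndarray:
        """All samples as (n_arms * n_samples, 2)."""
        return self.arm_coords.reshape(-1, 2)

    def arm_start_angles(self) -> np.ndarray:
        """Azimuthal angle of each arm (taken from its outermost sample)."""
        tip = self.arm_coords[:, -1]
        return np.mod(np.arctan2(tip[:, 1], tip[:, 0]), 2 * np.pi)

    def rotated(self, offset: float) -> "SpiralTrajectory":
        """Return a copy rotated by ``offset`` radians about the k-space origin."""
        c, s = np.cos(offset), np.sin(offset)
        rot = np.array([[c, -s], [s, c]])
        coords = self.arm_coords @ rot.T
        return replace(self, arm_coords=coords,
                       rotation_offset=self.rotation_offset + offset)


@dataclass(frozen=True)
class GradientTransferFunction:
    """Linear-system model of the gradient chain, one response per axis.

    The measured gradient system transfer function maps nominal gradient
    waveforms to the waveforms actually played out; applying it in
    post-correction yields the trajectory the scanner realized.
    """

    frequency_hz: np.ndarray
    response: np.ndarray  # (n_axes, n_freq) complex

    def __post_init__(self):
        f = np.asarray(self.frequency_hz, dtype=float)
        h = np.atleast_2d(np.asarray(self.response))
        if f.ndim != 1 or np.any(np.diff(f) <= 0):
            raise ParameterError("frequency axis must be strictly increasing")
        if h.shape[-1] != f.size:
            raise ParameterError("response length must match frequency axis")
        i0 = int(np.argmin(np.abs(f)))
        if np.any(np.abs(h[:, i0]) > 1 + 1e-9):
            raise ParameterError("response magnitude at DC must not exceed 1")
        object.__setattr__(self, "frequency_hz", f)
        object.__setattr__(self, "response", h)


def synthetic_gstf(n_axes: int = 2, delay_s: float = 2e-6,
                   cutoff_hz: float = 40e3, f_max_hz: float = 250e3,
                   n_freq: int = 512) -> GradientTransferFunction:
    """A plausible stand-in transfer function: small delay + first-order low-pass.

    Synthetic by construction -- it exercises the correction machinery without
    a measured system response.
    """
    f = np.linspace(0.0, f_max_hz, n_freq)
    h = np.exp(-2j * np.pi * f * delay_s) / (1 + 1j * f / cutoff_hz)
    return GradientTransferFunction(f, np.tile(h, (n_axes, 1)))


def _undersampling_profile(center: float, edge: float, kmax: float = 0.5):
    """Linear azimuthal undersampling law R(|k|) from center to edge."""
    def profile(k):
        return center + (edge - center) * np.clip(np.abs(k) / kmax, 0.0, 1.0)
    return profile


def design_spiral(fov_mm: float = 592.0, resolution_mm: float = 1.29,
                  n_arms: int = 13, center_undersampling: float = 5.0,
                  edge_undersampling: float = 15.0, n_samples: int | None = None,
                  tr_s: float = 3.7e-3, readout_duty: float = 0.70,
                  pixel_bandwidth_hz: float = 407.0,
                  matrix: int | None = None) -> SpiralTrajectory:
    """Design the variable-density center-out spiral pattern.

    The azimuthal undersampling factor R(|k|) -- the number of interleaves
    Nyquist sampling would require at radius |k|, divided by ``n_arms`` --
    follows a linear law from ``center_undersampling`` at the k-space
    origin to ``edge_undersampling`` at ``|k| = kmax``.  The interleaf is
    obtained by integrating ``dk/dtheta = n_arms * R(k) / (2*pi*N)`` with
    N = FOV/resolution, then resampling to constant arc-length spacing
    (constant readout speed) over ``n_samples`` points.

    When ``n_samples`` is not given it is derived from the readout timing:
    dwell = 1 / (pixel_bandwidth * matrix) and readout = TR * duty.
    """
    if fov_mm <= 0 or resolution_mm <= 0:
        raise ParameterError("fov_mm and resolution_mm must be positive")
    if n_arms < 1:
        raise ParameterError("n_arms must be >= 1")

    n_fov = fov_mm / resolution_mm
    if matrix is None:
        matrix = int(2 ** np.ceil(np.log2(n_fov)))  # 512 for the default geometry
    dwell = 1.0 / (pixel_bandwidth_hz * matrix)
    if n_samples is None:
        n_samples = int(round(tr_s * readout_duty / dwell))

    kmax = 0.5
    profile = _undersampling_profile(center_undersampling, edge_undersampling, kmax)

    # Integrate k(theta) on a fine radius grid: theta(k) = c * int dk'/R(k')
    # with c = 2*pi*N/n_arms; closed form exists for the linear law but the
    # quadrature keeps the profile pluggable.
    k_fine = np.linspace(0.0, kmax, 4096)
    inv_r = 1.0 / profile(k_fine)
    theta_fine = (2 * np.pi * n_fov / n_arms) * np.concatenate(
        ([0.0], np.cumsum(0.5 * (inv_r[1:] + inv_r[:-1]) * np.diff(k_fine))))

    x = k_fine * np.cos(theta_fine)
    y = k_fine * np.sin(theta_fine)
    seg = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate(([0.0], np.cumsum(seg)))
    s_eq = np.linspace(0.0, s[-1], n_samples)
    k_eq = interp1d(s, k_fine)(s_eq)
    th_eq = interp1d(s, theta_fine)(s_eq)

    arm0 = np.stack([k_eq * np.cos(th_eq), k_eq * np.sin(th_eq)], axis=-1)
    angles = 2 * np.pi * np.arange(n_arms) / n_arms
    cos_a, sin_a = np.cos(angles), np.sin(angles)
    arms = np.empty((n_arms, n_samples, 2))
    arms[:, :, 0] = arm0[None, :, 0] * cos_a[:, None] - arm0[None, :, 1] * sin_a[:, None]
    arms[:, :, 1] = arm0[None, :, 0] * sin_a[:, None] + arm0[None, :, 1] * cos_a[:, None]

    return SpiralTrajectory(arm_coords=arms, n_arms=n_arms, dwell_time=dwell,
                            rotation_offset=0.0, fov_mm=fov_mm,
                            resolution_mm=resolution_mm,
                            center_undersampling=center_undersampling,
                            edge_undersampling=edge_undersampling)


def measure_undersampling(traj: SpiralTrajectory, radius: float) -> float:
    """Azimuthal undersampling factor of a trajectory at a given |k|.

    Estimated from the designed interleaf as R = 2*pi*N*(dk/dtheta) / n_arms,
    with dk/dtheta finite-differenced along arm 0 and evaluated at the sample
    closest to ``radius``.
    """
    arm = traj.arm_coords[0]
    k = np.hypot(arm[:, 0], arm[:, 1])
    theta = np.unwrap(np.arctan2(arm[:, 1], arm[:, 0]))
    # skip the origin sample where the angle is undefined
    k, theta = k[1:], theta[1:]
    dk_dth = np.gradient(k, theta)
    idx = int(np.argmin(np.abs(k - radius)))
    n_req = 2 * np.pi * traj.fov_pixels * dk_dth[idx]
    return float(n_req / traj.n_arms)


def rotation_schedule(n_patterns: int, n_arms: int = 13) -> np.ndarray:
    """Rotation offsets (radians) that successively bisect the largest gap.

    The first pattern is unrotated.  Each further pattern is rotated so its
    arms land in the middle of the currently largest angular gap of the
    union of all arm angles so far; ties are broken by the smallest gap
    start angle.  Because a pattern occupies every multiple of 2*pi/n_arms,
    offsets are reported modulo that period.
    """
    if n_patterns < 1:
        raise ParameterError("n_patterns must be >= 1")
    period = 2 * np.pi / n_arms
    offsets = [0.0]
    for _ in range(1, n_patterns):
        angles = np.sort(np.unique(np.concatenate(
            [np.mod(off + np.arange(n_arms) * period, 2 * np.pi)
             for off in offsets])))
        gaps = np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]]))
        best = np.flatnonzero(gaps > gaps.max() - 1e-12)
        i = best[np.argmin(angles[best])]
        mid = angles[i] + gaps[i] / 2.0
        offsets.append(float(np.mod(mid, period)))
    return np.asarray(offsets)


def apply_gstf(gradient_waveform: np.ndarray, gstf: GradientTransferFunction,
               dt: float) -> np.ndarray:
    """Filter gradient waveforms with the system transfer function.

    The waveform spectrum is multiplied by the (interpolated) complex
    response and transformed back; the result is real-valued.  Waveforms
    are given as (n_axes, n_t) or (n_t,), uniformly sampled at ``dt``.
    """
    g = np.atleast_2d(np.asarray(gradient_waveform, dtype=float))
    n_t = g.shape[-1]
    freqs = np.fft.rfftfreq(n_t, d=dt)
    if freqs[-1] > gstf.frequency_hz[-1] + 1e-9:
        warnings.warn("waveform bandwidth exceeds GSTF support; response "
                      "extrapolated by its edge value", stacklevel=2)
    out = np.empty_like(g)
    for ax in range(g.shape[0]):
        h = gstf.response[min(ax, gstf.response.shape[0] - 1)]
        h_i = np.interp(freqs, gstf.frequency_hz, h.real) + \
            1j * np.interp(freqs, gstf.frequency_hz, h.imag)
        out[ax] = np.fft.irfft(np.fft.rfft(g[ax]) * h_i, n=n_t)
    return out if np.asarray(gradient_waveform).ndim > 1 else out[0]


def gradients_to_kspace(gradient_waveform: np.ndarray, dt: float,
                        gyromagnetic_ratio: float = GAMMA_PROTON) -> np.ndarray:
    """Cumulative zeroth-moment integration: k(t) = gamma * int_0^t G dt'.

    k(0) = 0; trapezoidal rule.  Shapes follow :func:`apply_gstf`.
    """
    g = np.atleast_2d(np.asarray(gradient_waveform, dtype=float))
    if not np.all(np.isfinite(g)):
        raise ParameterError("gradient waveform must be finite")
    k = np.zeros_like(g)
    k[:, 1:] = np.cumsum(0.5 * (g[:, 1:] + g[:, :-1]) * dt, axis=-1)
    k *= gyromagnetic_ratio
    return k if np.asarray(gradient_waveform).ndim > 1 else k[0]


def triangular_rewinder(gradient_waveform: np.ndarray, dt: float,
                        n_ramp: int = 32) -> np.ndarray:
    """Append a triangular lobe nulling the zeroth gradient moment.

    Returns the waveform with 2*n_ramp extra samples per axis whose
    integral cancels the accumulated moment of the readout, so the
    trajectory returns to the k-space origin.
    """
    g = np.atleast_2d(np.asarray(gradient_waveform, dtype=float))
    moment = np.trapezoid(g, dx=dt, axis=-1)
    tri = np.concatenate([np.linspace(0, 1, n_ramp, endpoint=False),
                          np.linspace(1, 0, n_ramp)])
    tri_area = np.trapezoid(tri, dx=dt)
    # the junction trapezoid between the last readout sample and the lobe
    # start (zero) contributes 0.5 * g_last * dt to the integral
    needed = -(moment + 0.5 * g[:, -1] * dt)
    lobe = needed[:, None] * tri[None, :] / tri_area
    out = np.concatenate([g, lobe], axis=-1)
    return out if np.asarray(gradient_waveform).ndim > 1 else out[0]


def density_compensation(traj: SpiralTrajectory) -> np.ndarray:
    """Per-sample density-compensation weights for gridding reconstruction.

    Geometric estimate of the k-space area owned by each sample: the
    along-track arc spacing of the sample on its arm times the cross-track
    spacing, taken as the distance to the nearest sample on any *other*
    arm.  For a radial-spoke distribution this is proportional to |k| away
    from the center, with a finite floored weight at the origin where arms
    coincide.  Weights are positive and normalized to unit mean.
    """
    from scipy.spatial import cKDTree

    arms = traj.arm_coords
    n_arms, n_samp, _ = arms.shape
    if n_arms * n_samp == 1:
        return np.ones(1)

    seg = np.linalg.norm(np.diff(arms, axis=1), axis=-1)  # (A, S-1)
    ds = np.empty((n_arms, n_samp))
    if n_samp > 1:
        ds[:, 0] = seg[:, 0]
        ds[:, -1] = seg[:, -1]
        ds[:, 1:-1] = 0.5 * (seg[:, 1:] + seg[:, :-1])
    else:
        ds[:] = 1.0

    if n_arms > 1:
        cross = np.empty((n_arms, n_samp))
        flat = arms.reshape(-1, 2)
        for a in range(n_arms):
            others = np.delete(flat.reshape(n_arms, n_samp, 2), a, axis=0)
            tree = cKDTree(others.reshape(-1, 2))
            cross[a], _ = tree.query(arms[a])
    else:
        cross = np.ones((n_arms, n_samp))

    w = (ds * np.maximum(cross, 0.25 * ds)).reshape(-1)
    w = np.maximum(w, 1e-6 * np.median(w[w > 0]) if np.any(w > 0) else 1e-12)
    w /= w.mean()
    return w
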