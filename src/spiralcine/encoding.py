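"""Non-uniform Fourier encoding, coil sensitivities, gridding and CG-SENSE.

The encoding model is y_c = F_k (S_c x): each coil image (sensitivity map
S_c times the object x) is sampled at the non-Cartesian spiral k-space
locations by a non-uniform Fourier transform.  Two evaluation paths are
provided: a Kaiser-Bessel convolution-gridding NUFFT (2x oversampled FFT
plus sparse interpolation) for speed, and an explicit DFT-sum mode that is
exact and serves as the numerical reference on small grids.

The interim image of the reconstruction chain is obtained by 10 conjugate-
gradient iterations on the normal equations of this system (CG-SENSE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import ndimage

from .trajectory import SpiralTrajectory, density_compensation


class ShapeError(ValueError):
    """Image / coil / k-space geometry mismatch."""


@dataclass(frozen=True)
class CoilSensitivities:
    """Complex receive sensitivity map per coil, shape (n_coils, N, N)."""

    maps: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.maps, dtype=np.complex128)
        if m.ndim != 3:
            raise ShapeError("coil maps must be (n_coils, N, N)")
        if not np.all(np.isfinite(m)):
            raise ShapeError("coil maps must be finite")
        object.__setattr__(self, "maps", m)

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def grid(self) -> int:
        return self.maps.shape[1]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


@dataclass
class KSpaceBundle:
    """Complex samples indexed (arm, readout point, coil) with timestamps."""

    samples: np.ndarray          # (n_arms, n_samples, n_coils)
    arm_times: np.ndarray        # (n_arms,) seconds, non-decreasing
    traj: SpiralTrajectory
    traj_ref: str = "default"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        self.arm_times = np.asarray(self.arm_times, dtype=float)
        if self.samples.ndim != 3:
            raise ShapeError("samples must be (n_arms, n_readout, n_coils)")
        if self.arm_times.shape[0] != self.samples.shape[0]:
            raise ShapeError("one timestamp per arm required")
        if np.any(np.diff(self.arm_times) < 0):
            raise ShapeError("arm timestamps must be non-decreasing")

    @property
    def n_arms(self) -> int:
        return self.samples.shape[0]

    @property
    def n_coils(self) -> int:
        return self.samples.shape[2]


def _kb_beta(width: int, oversampling: float) -> float:
    # Beatty et al. optimal shape parameter for minimal aliasing error
    a = oversampling
    return np.pi * np.sqrt((width / a) ** 2 * (a - 0.5) ** 2 - 0.8)


class NufftOperator:
    """Single-coil non-uniform Fourier transform for one trajectory/grid.

    Parameters
    ----------
    traj : SpiralTrajectory
        Sample locations, normalized to cycles/pixel in [-0.5, 0.5].
    grid : int
        Image matrix size N (image is N x N).
    mode : {"gridding", "exact"}
        "gridding" uses Kaiser-Bessel interpolation on a 2x oversampled
        FFT; "exact" evaluates the DFT sum directly (small grids only).
    width : int
        Interpolation kernel full width in oversampled grid cells.
    """

    def __init__(self, traj: SpiralTrajectory, grid: int, mode: str = "gridding",
                 oversampling: float = 2.0, width: int = 6):
        self.traj = traj
        self.grid = int(grid)
        self.mode = mode
        self.pts = traj.flat_coords()
        n = self.grid
        if mode == "exact":
            if n > 96:
                raise ShapeError("exact DFT mode is limited to grids <= 96")
            c = np.arange(n) - n // 2
            ph_x = np.exp(-2j * np.pi * np.outer(self.pts[:, 1], c))  # kx pairs with column index
            ph_y = np.exp(-2j * np.pi * np.outer(self.pts[:, 0], c))  # ky with row index
            # E[s, (r, col)] = ph_y[s, r] * ph_x[s, col]
            self._E = (ph_y[:, :, None] * ph_x[:, None, :]).reshape(len(self.pts), -1)
        elif mode == "gridding":
            self.m = int(round(oversampling * n))
            self.width = width
            self.beta = _kb_beta(width, self.m / n)
            self._P = self._build_interpolator()
            self._deapod = self._build_deapodization()
        else:
            raise ValueError(f"unknown NUFFT mode {mode!r}")

    # -- gridding internals -------------------------------------------------
    def _kernel(self, d: np.ndarray) -> np.ndarray:
        x = 1 - (2 * d / self.width) ** 2
        out = np.zeros_like(d)
        ok = x > 0
        out[ok] = np.i0(self.beta * np.sqrt(x[ok]))
        return out

    def _build_interpolator(self) -> sp.csr_matrix:
        m, w = self.m, self.width
        # row index = k-space coordinate 0 of image rows; u = k * m on the
        # centered oversampled spectrum, shifted to FFT index space
        u = self.pts * m  # (n, 2) in centered grid units
        half = w // 2
        rows, cols, vals = [], [], []
        offs = np.arange(-half, half + 1)
        base = np.rint(u).astype(int)
        n_pts = u.shape[0]
        idx = np.arange(n_pts)
        for dy in offs:
            gy = base[:, 0] + dy
            wy = self._kernel(np.abs(u[:, 0] - gy))
            for dx in offs:
                gx = base[:, 1] + dx
                wx = self._kernel(np.abs(u[:, 1] - gx))
                w2 = wy * wx
                keep = w2 > 0
                gyi = np.mod(gy[keep] + m // 2, m)
                gxi = np.mod(gx[keep] + m // 2, m)
                rows.append(idx[keep])
                cols.append(gyi * m + gxi)
                vals.append(w2[keep])
        P = sp.coo_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n_pts, m * m))
        return P.tocsr()

    def _build_deapodization(self) -> np.ndarray:
        # image-domain correction = continuous FT of the KB kernel,
        # evaluated by dense quadrature (separable)
        m, n = self.m, self.grid
        uu = np.linspace(-self.width / 2, self.width / 2, 2001)
        ker = self._kernel(np.abs(uu))
        x = np.arange(n) - n // 2
        c = (ker[None, :] * np.cos(2 * np.pi * np.outer(x, uu) / m)).sum(axis=1)
        c *= (uu[1] - uu[0])
        return np.outer(c, c)

    # -- public interface ---------------------------------------------------
    def forward(self, image: np.ndarray) -> np.ndarray:
        """Sample the image's Fourier transform at the trajectory points."""
        img = np.asarray(image, dtype=np.complex128)
        if img.shape != (self.grid, self.grid):
            raise ShapeError(f"image must be {self.grid}x{self.grid}")
        if self.mode == "exact":
            return self._E @ img.ravel()
        m, n = self.m, self.grid
        pad = np.zeros((m, m), dtype=np.complex128)
        lo = m // 2 - n // 2
        pad[lo:lo + n, lo:lo + n] = img / self._deapod
        spec = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(pad)))
        return self._P @ spec.ravel()

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`forward` (conjugate-transpose operator)."""
        y = np.asarray(samples, dtype=np.complex128).ravel()
        if y.shape[0] != self.pts.shape[0]:
            raise ShapeError("sample count mismatch")
        if self.mode == "exact":
            return (self._E.conj().T @ y).reshape(self.grid, self.grid)
        m, n = self.m, self.grid
        spec = (self._P.T @ y).reshape(m, m)
        img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(spec))) * (m * m)
        lo = m // 2 - n // 2
        return img[lo:lo + n, lo:lo + n] / self._deapod


def nufft_forward(image: np.ndarray, coils: CoilSensitivities,
                  traj: SpiralTrajectory, mode: str = "gridding",
                  op: NufftOperator | None = None) -> KSpaceBundle:
    """Per-coil spiral k-space samples of a coil-weighted image."""
    img = np.asarray(image, dtype=np.complex128)
    if img.shape != coils.maps.shape[1:]:
        raise ShapeError("image grid must match coil maps")
    if op is None:
        op = NufftOperator(traj, img.shape[0], mode=mode)
    n_arms, n_samp = traj.arm_coords.shape[:2]
    out = np.empty((n_arms, n_samp, coils.n_coils), dtype=np.complex128)
    for c in range(coils.n_coils):
        out[:, :, c] = op.forward(coils.maps[c] * img).reshape(n_arms, n_samp)
    times = np.arange(n_arms) * traj.dwell_time * n_samp
    return KSpaceBundle(out, times, traj)


def nufft_adjoint(kspace: KSpaceBundle, coils: CoilSensitivities,
                  traj: SpiralTrajectory | None = None, use_dcf: bool = True,
                  mode: str = "gridding", op: NufftOperator | None = None,
                  eps: float = 1e-8) -> np.ndarray:
    """Density-compensated gridding image with adaptive coil combination.

    Applies the NUFFT adjoint per coil (optionally after density
    compensation) and combines coils by conjugate-sensitivity weighting
    normalized by the sum of squared magnitudes.
    """
    traj = traj if traj is not None else kspace.traj
    if op is None:
        op = NufftOperator(traj, coils.grid, mode=mode)
    y = kspace.samples.reshape(-1, kspace.n_coils).copy()
    if use_dcf:
        y *= density_compensation(traj)[:, None]
    num = np.zeros((coils.grid, coils.grid), dtype=np.complex128)
    for c in range(coils.n_coils):
        num += np.conj(coils.maps[c]) * op.adjoint(y[:, c])
    den = np.sum(np.abs(coils.maps) ** 2, axis=0) + eps
    return num / den


def simulate_coils(grid: int, n_coils: int, seed: int = 0,
                   smoothness: float = 1.0) -> CoilSensitivities:
    """Smooth synthetic receive sensitivities around the field of view.

    Each coil is a broad Gaussian lobe centered on a ring just outside the
    image, with a gentle linear phase ramp; centers, widths and phases are
    jittered by the seed.  ``smoothness=np.inf`` collapses every map to a
    constant (useful for single-coil analytic tests).
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    rng = np.random.default_rng(seed)
    if np.isinf(smoothness):
        return CoilSensitivities(np.ones((n_coils, grid, grid), dtype=complex))
    yy, xx = np.mgrid[0:grid, 0:grid]
    cy0, cx0 = (grid - 1) / 2, (grid - 1) / 2
    maps = np.empty((n_coils, grid, grid), dtype=np.complex128)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.uniform(-0.3, 0.3)
        r = grid * (0.55 + rng.uniform(-0.05, 0.05))
        cy = cy0 + r * np.sin(ang)
        cx = cx0 + r * np.cos(ang)
        sigma = grid * (0.6 + rng.uniform(-0.1, 0.1)) / smoothness
        mag = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))
        ramp = (rng.uniform(-0.5, 0.5) * (yy - cy0) +
                rng.uniform(-0.5, 0.5) * (xx - cx0)) * 2 * np.pi / grid
        phase = ramp + rng.uniform(0, 2 * np.pi)
        maps[c] = mag * np.exp(1j * phase)
    # keep the root-sum-of-squares well conditioned over the FOV
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= max(rss.max(), 1e-12)
    maps += 0.05 * np.exp(1j * rng.uniform(0, 2 * np.pi))
    return CoilSensitivities(maps)


def estimate_coils_adaptive(coil_images: np.ndarray, block_size: int = 8,
                            subsample_factor: int = 1) -> CoilSensitivities:
    """Adaptive (Walsh-style) coil-map estimation from per-coil images.

    The per-pixel coil covariance is formed by block-smoothing the outer
    products of the coil images; the dominant eigenvector gives the
    sensitivity direction, normalized to unit root-sum-of-squares and
    phase-referenced to the first coil.  ``subsample_factor`` estimates on
    a decimated grid and interpolates back, trading accuracy for speed.
    """
    imgs = np.asarray(coil_images, dtype=np.complex128)
    if imgs.ndim != 3:
        raise ShapeError("coil images must be (n_coils, N, N)")
    if np.allclose(imgs, 0):
        raise ValueError("all-zero coil images: cannot estimate sensitivities")
    n_coils, n, _ = imgs.shape
    f = max(int(subsample_factor), 1)
    work = imgs[:, ::f, ::f]
    bs = max(block_size // f, 1)
    nn = work.shape[1]
    # covariance R_ij(x) = <m_i(x) conj(m_j(x))> over a local block
    cov = np.empty((nn, work.shape[2], n_coils, n_coils), dtype=np.complex128)
    for i in range(n_coils):
        for j in range(n_coils):
            prod = work[i] * np.conj(work[j])
            sm = ndimage.uniform_filter(prod.real, bs) + \
                1j * ndimage.uniform_filter(prod.imag, bs)
            cov[:, :, i, j] = sm
    vals, vecs = np.linalg.eigh(cov)
    dom = vecs[..., -1]                      # (ny, nx, n_coils)
    dom = np.moveaxis(dom, -1, 0)            # (n_coils, ny, nx)
    # unit RSS by construction of eigh; fix the per-pixel phase gauge
    ref = dom[0]
    phase = np.exp(-1j * np.angle(np.where(np.abs(ref) > 0, ref, 1.0)))
    dom = dom * phase[None]
    if f > 1:
        full = np.empty((n_coils, n, imgs.shape[2]), dtype=np.complex128)
        zy = n / dom.shape[1]
        zx = imgs.shape[2] / dom.shape[2]
        for c in range(n_coils):
            full[c] = (ndimage.zoom(dom[c].real, (zy, zx), order=1) +
                       1j * ndimage.zoom(dom[c].imag, (zy, zx), order=1))
        dom = full
        rss = np.sqrt(np.sum(np.abs(dom) ** 2, axis=0))
        dom /= np.maximum(rss, 1e-12)
    return CoilSensitivities(dom)


class DivergenceError(RuntimeError):
    """CG iterate became non-finite."""


def cg_sense(kspace: KSpaceBundle, traj: SpiralTrajectory | None = None,
             coils: CoilSensitivities | None = None, n_iter: int = 10,
             mode: str = "gridding", weights: np.ndarray | None = None,
             op: NufftOperator | None = None,
             return_residuals: bool = False):
    """Interim image estimate by CG on the SENSE normal equations.

    Solves A^H A x = A^H y with A the coil-weighted NUFFT, by plain
    (unregularized, unpreconditioned) conjugate gradients, returning the
    iterate after ``n_iter`` steps.  ``weights`` optionally applies
    per-sample weighting w (then A^H W A x = A^H W y).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    traj = traj if traj is not None else kspace.traj
    if coils is None:
        raise ValueError("coil sensitivities required")
    n = coils.grid
    if op is None:
        op = NufftOperator(traj, n, mode=mode)
    maps = coils.maps
    y = kspace.samples.reshape(-1, kspace.n_coils)

    def A(x):
        return np.stack([op.forward(maps[c] * x) for c in range(maps.shape[0])],
                        axis=-1)

    def AH(s):
        out = np.zeros((n, n), dtype=np.complex128)
        for c in range(maps.shape[0]):
            out += np.conj(maps[c]) * op.adjoint(s[:, c])
        return out

    w = weights[:, None] if weights is not None else 1.0

    def normal(x):
        return AH(w * A(x))

    b = AH(w * y)
    x = np.zeros((n, n), dtype=np.complex128)
    r = b.copy()
    p = r.copy()
    rs = np.vdot(r, r).real
    residuals = [np.sqrt(rs)]
    for it in range(n_iter):
        Ap = normal(p)
        denom = np.vdot(p, Ap).real
        if denom <= 0 or not np.isfinite(denom):
            break
        alpha = rs / denom
        x = x + alpha * p
        if not np.all(np.isfinite(x)):
            raise DivergenceError(f"CG-SENSE iterate non-finite at iteration {it + 1}")
        r = r - alpha * Ap
        rs_new = np.vdot(r, r).real
        residuals.append(np.sqrt(rs_new))
        p = r + (rs_new / rs) * p
        rs = rs_new
    if return_residuals:
        return x, np.asarray(residuals)
    return x
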