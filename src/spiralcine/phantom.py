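"""Synthetic dynamic short-axis cardiac phantom and raw-data simulation.

The phantom stands in for both training sources of the joint
reconstruction/segmentation model: image+mask pairs from which
undersampled spiral raw data are simulated (random coil sensitivities +
forward NUFFT + CG-SENSE interim), and multi-heartbeat breath-hold spiral
sessions from which both real-time frames and self-gated segmented
k-spaces can be derived.  Free-breathing sessions add respiratory
translation and RR variability (arrhythmia).

Geometry: concentric ellipses for the LV blood pool and myocardium, a
crescent for the RV, and a chest-wall fat band; all regions have analytic
areas, so ejection fraction has a closed-form ground truth.  Masks are
pixelized area-preservingly: within each region the pixels with the
highest sub-pixel coverage are selected until the rounded analytic
coverage is reached, so mask pixel counts track analytic areas to within
one pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .encoding import (CoilSensitivities, KSpaceBundle, NufftOperator,
                       cg_sense, nufft_forward, simulate_coils)
from .trajectory import SpiralTrajectory, rotation_schedule

LABEL_BACKGROUND, LABEL_LV, LABEL_MYO, LABEL_RV = 0, 1, 2, 3


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomConfig:
    """Anatomy, timing and noise parameters of the synthetic heart."""

    grid: int = 128
    pixel_mm: float = 2.0
    slice_thickness_mm: float = 8.0
    lv_endo_ed_mm: float = 24.0       # LV endocardial radius at end-diastole
    lv_endo_es_mm: float = 16.0       # ... at end-systole
    wall_ed_mm: float = 9.0           # myocardial wall thickness at ED
    rv_radius_mm: float = 22.0        # RV crescent outer radius
    rv_offset_mm: float = 30.0        # RV center offset from LV center
    intensity_blood: float = 1.0
    intensity_myo: float = 0.40
    intensity_fat: float = 0.75
    intensity_background: float = 0.05
    rr_mean_s: float = 1.0
    rr_variability: float = 0.0       # lognormal sigma; 0 = regular rhythm
    respiration_amplitude_mm: float = 0.0
    respiration_period_s: float = 4.0
    systole_fraction: float = 0.35    # phase fraction at which ES occurs
    noise_level: float = 0.0          # k-space noise as fraction of DC magnitude
    seed: int = 0

    def __post_init__(self):
        if self.lv_endo_es_mm > self.lv_endo_ed_mm:
            raise GeometryError("ES radius must not exceed ED radius")
        if min(self.intensity_blood, self.intensity_myo, self.intensity_fat,
               self.intensity_background) < 0:
            raise GeometryError("intensities must be non-negative")
        if not (0 <= self.rr_variability < 1):
            raise GeometryError("rr_variability must be in [0, 1)")
        extent = (self.rv_offset_mm + self.rv_radius_mm) * 2
        if extent >= self.grid * self.pixel_mm:
            raise GeometryError("phantom geometry exceeds the image grid")

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_mm ** 2

    def analytic_ef(self) -> float:
        """Area-based ejection fraction implied by the configured radii."""
        a_ed = np.pi * self.lv_endo_ed_mm ** 2
        a_es = np.pi * self.lv_endo_es_mm ** 2
        return 100.0 * (a_ed - a_es) / a_ed


@dataclass
class PhantomFrame:
    """One short-axis frame with ground-truth labels."""

    image: np.ndarray           # magnitude, (grid, grid)
    mask: np.ndarray            # labels {0 bg, 1 LV, 2 myo, 3 RV}
    time_s: float
    phase_fraction: float       # cardiac phase in [0, 1), 0 = end-diastole
    lv_area_mm2: float          # analytic (sub-pixel coverage) LV area


def _contraction(phase: np.ndarray | float, systole_fraction: float) -> np.ndarray:
    """Raised-cosine contraction law: 0 at ED (phase 0), 1 at ES."""
    p = np.asarray(phase, dtype=float)
    fs = systole_fraction
    g = np.where(p < fs, 0.5 * p / fs, 0.5 + 0.5 * (p - fs) / (1 - fs))
    return 0.5 * (1 - np.cos(2 * np.pi * g))


def _coverage_disk(cfg: PhantomConfig, cy: float, cx: float, r_px: float,
                   ss: int = 8) -> np.ndarray:
    """Sub-pixel coverage of a disk, supersampled ss x ss per pixel."""
    n = cfg.grid
    g = (np.arange(n * ss) + 0.5) / ss - 0.5
    yy = (g - cy)[:, None] ** 2
    xx = (g - cx)[None, :] ** 2
    inside = (yy + xx) <= r_px ** 2
    return inside.reshape(n, ss, n, ss).mean(axis=(1, 3))


def _area_preserving_mask(coverage: np.ndarray, exclude: np.ndarray | None = None
                          ) -> np.ndarray:
    """Boolean pixelization whose count equals round(sum coverage)."""
    cov = coverage.copy()
    if exclude is not None:
        cov[exclude] = 0.0
    k = int(round(cov.sum()))
    if k <= 0:
        return np.zeros_like(cov, dtype=bool)
    flat = cov.ravel()
    order = np.argsort(flat)[::-1]
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(cov.shape) & (cov > 0)


def render_frame(cfg: PhantomConfig, phase_fraction: float, time_s: float = 0.0,
                 shift_mm: tuple[float, float] = (0.0, 0.0)) -> PhantomFrame:
    """Render one frame of the phantom at a given cardiac phase."""
    c = _contraction(phase_fraction, cfg.systole_fraction)
    px = cfg.pixel_mm
    r_endo = (cfg.lv_endo_ed_mm - (cfg.lv_endo_ed_mm - cfg.lv_endo_es_mm) * c) / px
    # myocardial cross-section area is conserved during contraction
    epi_ed = cfg.lv_endo_ed_mm + cfg.wall_ed_mm
    myo_area = epi_ed ** 2 - cfg.lv_endo_ed_mm ** 2
    r_epi = np.sqrt((r_endo * px) ** 2 + myo_area) / px

    n = cfg.grid
    cy = (n - 1) / 2 + shift_mm[0] / px
    cx = (n - 1) / 2 + shift_mm[1] / px
    rv_cx = cx - cfg.rv_offset_mm / px
    rv_r = (cfg.rv_radius_mm - 0.35 * (cfg.rv_radius_mm - 0.8 * cfg.rv_radius_mm) * c) / px

    cov_endo = _coverage_disk(cfg, cy, cx, r_endo)
    cov_epi = _coverage_disk(cfg, cy, cx, r_epi)
    cov_rv_disk = _coverage_disk(cfg, cy, rv_cx, rv_r)
    cov_rv_wall = _coverage_disk(cfg, cy, rv_cx, rv_r + 3.0 / px)

    lv = _area_preserving_mask(cov_endo)
    epi = _area_preserving_mask(cov_epi)
    myo = epi & ~lv
    rv = _area_preserving_mask(np.clip(cov_rv_disk - cov_epi - (cov_rv_wall - cov_rv_disk), 0, 1),
                               exclude=epi)

    mask = np.zeros((n, n), dtype=np.uint8)
    mask[rv] = LABEL_RV
    mask[myo] = LABEL_MYO
    mask[lv] = LABEL_LV

    # chest-wall fat band (intensity only, unlabeled)
    yy = np.arange(n)[:, None]
    fat_y0 = cy - (cfg.rv_offset_mm + cfg.rv_radius_mm + 8) / px
    fat = (np.abs((np.arange(n)[None, :] * 0 + yy) - fat_y0) < 4.0 / px) & \
        (np.ones((1, n), dtype=bool))

    img = np.full((n, n), cfg.intensity_background)
    img = np.where(fat, cfg.intensity_fat, img)
    # paint regions with anti-aliased blending, inner regions last
    rv_wall_cov = np.clip(cov_rv_wall - cov_rv_disk, 0, 1) * (1 - cov_epi)
    img = img * (1 - rv_wall_cov) + cfg.intensity_myo * rv_wall_cov
    rv_cov = np.clip(cov_rv_disk - cov_epi, 0, 1)
    img = img * (1 - rv_cov) + cfg.intensity_blood * rv_cov
    img = img * (1 - cov_epi) + cfg.intensity_myo * cov_epi
    img = img * (1 - cov_endo) + cfg.intensity_blood * cov_endo

    lv_area = float(cov_endo.sum() * cfg.pixel_area_mm2)
    return PhantomFrame(image=img, mask=mask, time_s=time_s,
                        phase_fraction=float(phase_fraction), lv_area_mm2=lv_area)


def generate_cine_phantom(cfg: PhantomConfig, n_frames: int) -> list[PhantomFrame]:
    """Frames uniformly covering one cardiac cycle (phase 0 = end-diastole)."""
    frames = []
    for f in range(n_frames):
        phase = f / n_frames
        frames.append(render_frame(cfg, phase, time_s=phase * cfg.rr_mean_s))
    return frames


def make_set1_pair(frame: PhantomFrame, traj: SpiralTrajectory, n_coils: int = 8,
                   seed: int = 0, n_iter: int = 10, noise_level: float = 0.0,
                   op: NufftOperator | None = None, estimate_maps: bool = False):
    """Simulated training pair: CG-SENSE interim input + clean targets.

    Random coil sensitivities are superimposed on the frame, spiral raw
    data are generated with the forward NUFFT, complex Gaussian noise is
    optionally added, and 10 CG-SENSE iterations produce the interim
    input image.  Targets are the original frame and its label mask.

    With ``estimate_maps`` the CG step uses Walsh-estimated (unit
    root-sum-of-squares) maps computed from the coil images instead of
    the generating maps — the same estimation path a reconstruction of
    acquired data goes through, including its intensity shading — so
    training inputs match deployment inputs.
    """
    grid = frame.image.shape[0]
    coils = simulate_coils(grid, n_coils, seed=seed)
    if op is None:
        op = NufftOperator(traj, grid)
    bundle = nufft_forward(frame.image, coils, traj, op=op)
    if noise_level > 0:
        rng = np.random.default_rng(seed + 1)
        dc = np.median(np.abs(bundle.samples[:, 0, :]))
        std = noise_level * dc
        bundle.samples += std * (rng.standard_normal(bundle.samples.shape) +
                                 1j * rng.standard_normal(bundle.samples.shape))
    if estimate_maps:
        from .encoding import estimate_coils_adaptive
        recon_coils = estimate_coils_adaptive(coils.maps * frame.image)
    else:
        recon_coils = coils
    interim = cg_sense(bundle, traj, recon_coils, n_iter=n_iter, op=op)
    return interim, frame.image.copy(), frame.mask.copy()


@dataclass
class Session:
    """A simulated acquisition: raw data plus full ground truth."""

    kspace: KSpaceBundle          # all acquired arms, session trajectory
    base_traj: SpiralTrajectory   # unrotated 13-arm pattern
    coils: CoilSensitivities
    frames: list[PhantomFrame]    # object truth, one per real-time frame
    frame_times: np.ndarray       # frame start times, seconds
    pattern_index: np.ndarray     # orientation index per frame
    rotation_offsets: np.ndarray
    triggers_s: np.ndarray        # ground-truth trigger times
    config: PhantomConfig
    mode: str = "breathhold"

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_kspace(self, f: int) -> KSpaceBundle:
        """The 13-arm real-time bundle of frame ``f`` with its rotated pattern."""
        na = self.base_traj.n_arms
        sl = slice(f * na, (f + 1) * na)
        traj = replace(self.base_traj,
                       arm_coords=self.kspace.traj.arm_coords[sl],
                       rotation_offset=float(self.rotation_offsets[self.pattern_index[f]]))
        return KSpaceBundle(self.kspace.samples[sl], self.kspace.arm_times[sl],
                            traj, traj_ref=f"frame{f}")


def simulate_session(cfg: PhantomConfig, mode: str = "breathhold",
                     duration_s: float = 10.0, n_patterns: int = 8,
                     n_coils: int = 8, traj: SpiralTrajectory | None = None,
                     tr_s: float = 3.7e-3) -> Session:
    """Simulate a spiral acquisition with pattern rotation and ground truth.

    Arms are emitted frame by frame (13 arms per 48-ms real-time frame);
    the object state is rendered once per frame at the frame start time.
    In breath-hold mode the pattern orientation advances at every
    heartbeat once it has been repeated for at least one full RR interval
    (one orientation per heartbeat, cycling after ``n_patterns``).  In
    free-breathing mode the orientation cycles frame-by-frame and a
    sinusoidal in-plane translation emulates respiration; RR intervals are
    drawn lognormally when ``rr_variability > 0`` (arrhythmia).
    """
    if mode not in ("breathhold", "freebreathing"):
        raise ValueError(f"unknown session mode {mode!r}")
    if duration_s < cfg.rr_mean_s:
        raise GeometryError("session duration must cover at least one RR interval")
    if traj is None:
        from .trajectory import design_spiral
        traj = design_spiral(fov_mm=cfg.grid * cfg.pixel_mm,
                             resolution_mm=cfg.pixel_mm, n_samples=256,
                             matrix=cfg.grid)
    rng = np.random.default_rng(cfg.seed)
    na = traj.n_arms
    frame_dt = na * tr_s
    n_frames = int(np.floor(duration_s / frame_dt))

    # ground-truth cardiac timeline
    triggers = [0.0]
    while triggers[-1] < duration_s + cfg.rr_mean_s:
        if cfg.rr_variability > 0:
            rr = cfg.rr_mean_s * rng.lognormal(0.0, cfg.rr_variability)
        else:
            rr = cfg.rr_mean_s
        triggers.append(triggers[-1] + rr)
    triggers = np.asarray(triggers)

    offsets = rotation_schedule(n_patterns, na)
    coils = simulate_coils(cfg.grid, n_coils, seed=cfg.seed + 17)
    ops = {}

    frame_times = np.arange(n_frames) * frame_dt
    beat_of_frame = np.searchsorted(triggers, frame_times, side="right") - 1
    if mode == "breathhold":
        pattern_index = np.mod(beat_of_frame, n_patterns)
    else:
        pattern_index = np.mod(np.arange(n_frames), n_patterns)

    frames = []
    all_samples = []
    all_coords = []
    arm_times = []
    for f in range(n_frames):
        t = frame_times[f]
        b = beat_of_frame[f]
        phase = (t - triggers[b]) / (triggers[b + 1] - triggers[b])
        if mode == "freebreathing" and cfg.respiration_amplitude_mm > 0:
            shift = (cfg.respiration_amplitude_mm *
                     np.sin(2 * np.pi * t / cfg.respiration_period_s), 0.0)
        else:
            shift = (0.0, 0.0)
        frame = render_frame(cfg, phase, time_s=t, shift_mm=shift)
        frames.append(frame)

        p = int(pattern_index[f])
        if p not in ops:
            rot = traj.rotated(offsets[p])
            ops[p] = (rot, NufftOperator(rot, cfg.grid))
        rot, op = ops[p]
        bundle = nufft_forward(frame.image, coils, rot, op=op)
        all_samples.append(bundle.samples)
        all_coords.append(rot.arm_coords)
        arm_times.append(t + np.arange(na) * tr_s)

    samples = np.concatenate(all_samples, axis=0)
    coords = np.concatenate(all_coords, axis=0)
    times = np.concatenate(arm_times)
    if cfg.noise_level > 0:
        dc = np.median(np.abs(samples[:, 0, :]))
        std = cfg.noise_level * dc
        samples = samples + std * (rng.standard_normal(samples.shape) +
                                   1j * rng.standard_normal(samples.shape))
    session_traj = replace(traj, arm_coords=coords)
    ks = KSpaceBundle(samples, times, session_traj, traj_ref="session")
    return Session(kspace=ks, base_traj=traj, coils=coils, frames=frames,
                   frame_times=frame_times, pattern_index=pattern_index,
                   rotation_offsets=offsets,
                   triggers_s=triggers[triggers <= duration_s],
                   config=cfg, mode=mode)
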