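"""Cardiac self-gating from the k-space center (DC) signal.

Every spiral arm starts at the k-space origin, so the first readout sample
of each arm is the DC value of the coil image — a free navigator that
pulsates with the cardiac cycle.  Triggers detected on this signal let the
same acquisition be used twice: binned into real-time frames, and sorted
into segmented (multi-heartbeat) k-spaces for a self-gated reference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .encoding import KSpaceBundle


class GatingError(RuntimeError):
    pass


@dataclass(frozen=True)
class GatingSignal:
    """Detrended DC magnitude per arm, with acquisition timestamps."""

    values: np.ndarray
    arm_times: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        t = np.asarray(self.arm_times, dtype=float)
        if v.shape != t.shape or v.ndim != 1:
            raise GatingError("values and arm_times must be matching 1-D arrays")
        if not np.all(np.isfinite(v)):
            raise GatingError("gating signal must be finite")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "arm_times", t)

    @property
    def sampling_rate(self) -> float:
        dt = np.median(np.diff(self.arm_times))
        return 1.0 / dt if dt > 0 else np.nan


@dataclass(frozen=True)
class CardiacPhaseBins:
    """Trigger times plus the (heartbeat, phase) assignment of each arm.

    ``assignment`` maps arm index -> (heartbeat index, phase index);
    arms outside accepted heartbeats carry (-1, -1).
    """

    trigger_times: np.ndarray
    n_phases: int
    assignment: np.ndarray  # (n_arms, 2) int
    discarded: np.ndarray   # bool per arm

    def __post_init__(self):
        t = np.asarray(self.trigger_times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise GatingError("trigger times must be strictly increasing")
        a = np.asarray(self.assignment, dtype=int)
        ph = a[:, 1]
        if np.any((ph >= self.n_phases) | ((ph < 0) & (ph != -1))):
            raise GatingError("phase indices out of range")
        object.__setattr__(self, "trigger_times", t)
        object.__setattr__(self, "assignment", a)
        object.__setattr__(self, "discarded", np.asarray(self.discarded, bool))

    @property
    def rr_intervals(self) -> np.ndarray:
        return np.diff(self.trigger_times)


def extract_dc(kspace: KSpaceBundle, detrend_window_s: float = 2.0) -> GatingSignal:
    """Root-sum-of-squares DC magnitude per arm, baseline-removed.

    Requires a center-out trajectory (first sample at |k| ~ 0).  The slow
    baseline (receiver drift, respiration at long windows) is removed by
    subtracting a moving-average over ``detrend_window_s`` seconds.
    """
    k0 = np.hypot(*kspace.traj.arm_coords[0, 0])
    if k0 > 1e-6:
        raise GatingError("trajectory is not center-out; no DC sample available")
    dc = np.sqrt(np.sum(np.abs(kspace.samples[:, 0, :]) ** 2, axis=-1))
    times = kspace.arm_times
    dt = np.median(np.diff(times)) if len(times) > 1 else 1.0
    win = max(int(round(detrend_window_s / dt)), 1)
    if win > 1 and len(dc) > win:
        pad = np.pad(dc, win // 2, mode="edge")
        kernel = np.ones(win) / win
        baseline = np.convolve(pad, kernel, mode="same")[win // 2: win // 2 + len(dc)]
        dc = dc - baseline
    elif np.any(dc):
        dc = dc - dc.mean()
    return GatingSignal(dc, times)


def detect_triggers(sig: GatingSignal, band: tuple[float, float] = (0.5, 3.0),
                    order: int = 4) -> np.ndarray:
    """Cardiac trigger times from the DC navigator.

    Two-stage detection: a zero-phase (forward-backward Butterworth)
    band-pass over the full cardiac ``band`` locates the dominant cardiac
    frequency f0; a second narrow band-pass around f0 suppresses
    harmonics of the pulsation waveform, and peaks are picked with a
    minimum separation of 0.6/f0.  Returns one trigger time per detected
    heartbeat.
    """
    fs = sig.sampling_rate
    duration = sig.arm_times[-1] - sig.arm_times[0]
    if duration < 2.0 / band[0]:
        raise GatingError("signal shorter than two cardiac periods")
    if np.std(sig.values) < 1e-12 * (np.abs(sig.values).mean() + 1.0):
        raise GatingError("insufficient heartbeats: gating signal is constant")
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    wide = sps.sosfiltfilt(sos, sig.values)
    spec = np.abs(np.fft.rfft(wide * np.hanning(len(wide))))
    freqs = np.fft.rfftfreq(len(wide), 1.0 / fs)
    in_band = (freqs >= lo) & (freqs <= hi)
    f0 = float(freqs[in_band][np.argmax(spec[in_band])])
    nlo, nhi = max(lo, 0.55 * f0), min(hi, 1.7 * f0)
    sos2 = sps.butter(2, [nlo, nhi], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos2, sig.values)
    min_sep = max(int(round(0.6 / f0 * fs)), 1)
    height = 0.2 * np.std(filt)
    peaks, _ = sps.find_peaks(filt, distance=min_sep, height=height)
    if len(peaks) < 2:
        raise GatingError("insufficient heartbeats: fewer than 2 triggers detected")
    # coarse-to-fine: the narrow band identifies beats, the wide band keeps
    # their timing; refine each peak to the local wide-band maximum
    half = max(int(round(0.25 / f0 * fs)), 1)
    refined = []
    for p in peaks:
        lo_i, hi_i = max(p - half, 0), min(p + half + 1, len(wide))
        refined.append(lo_i + int(np.argmax(wide[lo_i:hi_i])))
    refined = np.unique(refined)
    return sig.arm_times[refined]


def bin_arms(arm_times: np.ndarray, trigger_times: np.ndarray,
             n_phases: int = 20, rr_tolerance: float = 0.40) -> CardiacPhaseBins:
    """Assign every arm to a (heartbeat, cardiac phase) bin.

    The cardiac phase is the linear time fraction within the enclosing RR
    interval, quantized into ``n_phases`` bins.  Heartbeats whose RR lies
    outside median +/- ``rr_tolerance`` (fractional) are discarded, as are
    arms before the first / after the last trigger.
    """
    arm_times = np.asarray(arm_times, float)
    trig = np.asarray(trigger_times, float)
    rr = np.diff(trig)
    med = np.median(rr)
    good_beat = np.abs(rr - med) <= rr_tolerance * med
    assignment = np.full((len(arm_times), 2), -1, dtype=int)
    discarded = np.ones(len(arm_times), dtype=bool)
    idx = np.searchsorted(trig, arm_times, side="right") - 1
    for i, (t, b) in enumerate(zip(arm_times, idx)):
        if b < 0 or b >= len(rr) or not good_beat[b]:
            continue
        frac = (t - trig[b]) / rr[b]
        ph = min(int(frac * n_phases), n_phases - 1)
        assignment[i] = (b, ph)
        discarded[i] = False
    return CardiacPhaseBins(trig, n_phases, assignment, discarded)


def assemble_segmented(kspace: KSpaceBundle, bins: CardiacPhaseBins,
                       phase: int, n_heartbeats: int = 8,
                       pattern_arms: int = 13) -> KSpaceBundle:
    """Composite multi-heartbeat k-space for one cardiac phase.

    From each of ``n_heartbeats`` accepted heartbeats, the 13-arm pattern
    whose acquisition matches the requested phase is collected; because
    the pattern orientation rotates between heartbeats, the composite
    covers ``n_heartbeats * pattern_arms`` distinct arm angles (104 arms
    in the default eight-heartbeat configuration).
    """
    beats = np.unique(bins.assignment[~bins.discarded, 0])
    sel_arms = []
    used_beats = 0
    n_frames = kspace.n_arms // pattern_arms
    frame_beat = bins.assignment[:n_frames * pattern_arms, 0].reshape(
        n_frames, pattern_arms)
    frame_phase = bins.assignment[:n_frames * pattern_arms, 1].reshape(
        n_frames, pattern_arms)
    for b in beats:
        if used_beats == n_heartbeats:
            break
        # candidate frames lie entirely within this heartbeat, so the whole
        # 13-arm pattern shares one orientation
        cand = np.flatnonzero(np.all(frame_beat == b, axis=1))
        if cand.size == 0:
            continue
        mean_ph = frame_phase[cand].mean(axis=1)
        best = cand[np.argmin(np.abs(mean_ph - phase))]
        sel_arms.extend(range(best * pattern_arms, (best + 1) * pattern_arms))
        used_beats += 1
    if used_beats < n_heartbeats:
        raise GatingError(
            f"only {used_beats} usable heartbeats, need {n_heartbeats}")
    sel = np.asarray(sel_arms)
    samples = kspace.samples[sel]
    times = kspace.arm_times[sel]
    order = np.argsort(times)
    traj = kspace.traj
    n_samp = traj.arm_coords.shape[1]
    # rebuild the composite trajectory from the per-arm physical angles
    coords = _arm_coords_for(kspace, sel[order])
    comp_traj = replace(traj, arm_coords=coords)
    return KSpaceBundle(samples[order], times[order], comp_traj,
                        traj_ref=kspace.traj_ref + f"/segmented-phase{phase}")


def _arm_coords_for(kspace: KSpaceBundle, arm_indices: np.ndarray) -> np.ndarray:
    """Coordinates of specific acquired arms.

    Sessions store the full per-arm trajectory (pattern rotations already
    applied) when the arm count matches; otherwise arms are mapped onto
    the base pattern cyclically.
    """
    traj = kspace.traj
    if traj.arm_coords.shape[0] == kspace.n_arms:
        return traj.arm_coords[arm_indices]
    return traj.arm_coords[np.mod(arm_indices, traj.arm_coords.shape[0])]


def match_frames(frame_times: np.ndarray, bins: CardiacPhaseBins) -> np.ndarray:
    """Nearest self-gated cardiac phase for each real-time frame.

    Each frame time is converted to its phase fraction within the
    enclosing RR interval and mapped to the phase bin covering that
    fraction (bins partition [0, 1) uniformly, matching :func:`bin_arms`);
    a frame exactly on a trigger lands in phase 0, mid-RR in phase
    n_phases // 2.  Frames outside the triggered range clamp to the
    nearest RR interval.
    """
    trig = bins.trigger_times
    rr = np.diff(trig)
    out = np.empty(len(frame_times), dtype=int)
    for i, t in enumerate(np.asarray(frame_times, float)):
        b = int(np.clip(np.searchsorted(trig, t, side="right") - 1, 0, len(rr) - 1))
        frac = np.clip((t - trig[b]) / rr[b], 0.0, 1.0 - 1e-9)
        out[i] = min(int(frac * bins.n_phases), bins.n_phases - 1)
    return out
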