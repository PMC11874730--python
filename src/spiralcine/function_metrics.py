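"""Cardiac function quantification and image/mask quality metrics.

Real-time imaging covers several consecutive cardiac cycles per slice, so
end-diastolic and end-systolic volumes are taken as the *medians* of the
automatically detected local maxima and minima of the per-frame LV volume
curve — one corrupted cycle (arrhythmic beat, transient segmentation
failure) then barely moves the ejection fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from skimage.metrics import structural_similarity

from .phantom import LABEL_LV


class CurveError(RuntimeError):
    pass


@dataclass
class VolumeCurve:
    """Per-frame LV blood-pool volume with detected extrema."""

    times_s: np.ndarray
    volumes_ml: np.ndarray
    maxima_idx: np.ndarray = field(default_factory=lambda: np.array([], int))
    minima_idx: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, float)
        self.volumes_ml = np.asarray(self.volumes_ml, float)
        if np.any(self.volumes_ml < 0):
            raise CurveError("volumes must be non-negative")


def mask_volume(mask: np.ndarray, pixel_area_mm2: float,
                slice_thickness_mm: float = 8.0, label: int = LABEL_LV) -> float:
    """Single-slice volume in ml: label pixel count x pixel area x thickness."""
    count = int(np.sum(np.asarray(mask) == label))
    return count * pixel_area_mm2 * slice_thickness_mm / 1000.0


def volume_curve(masks: np.ndarray, times_s: np.ndarray, pixel_area_mm2: float,
                 slice_thickness_mm: float = 8.0) -> VolumeCurve:
    """Volume curve from a (n_frames, N, N) mask series."""
    vols = [mask_volume(m, pixel_area_mm2, slice_thickness_mm) for m in masks]
    return VolumeCurve(times_s, np.asarray(vols))


def detect_extrema(curve: VolumeCurve, min_separation_s: float = 0.3,
                   smooth_frames: int = 3) -> VolumeCurve:
    """Locate per-cycle volume maxima (ED) and minima (ES).

    The curve is lightly smoothed (moving average over ``smooth_frames``),
    peaks of both signs are picked with a minimum temporal separation, and
    alternation is enforced by dropping the lesser of adjacent same-type
    extrema.
    """
    v = curve.volumes_ml.astype(float)
    if len(v) < 3:
        raise CurveError("curve too short for extremum detection")
    if smooth_frames > 1:
        pad = np.pad(v, smooth_frames // 2, mode="edge")
        kernel = np.ones(smooth_frames) / smooth_frames
        v = np.convolve(pad, kernel, mode="valid")[:len(curve.volumes_ml)]
    dt = np.median(np.diff(curve.times_s))
    dist = max(int(round(min_separation_s / dt)), 1)
    maxima, _ = sps.find_peaks(v, distance=dist)
    minima, _ = sps.find_peaks(-v, distance=dist)
    if len(maxima) == 0 or len(minima) == 0:
        raise CurveError("no extrema found (monotone or flat volume curve)")

    # enforce alternation: of two consecutive same-type extrema keep the
    # more extreme one
    events = sorted([(i, +1) for i in maxima] + [(i, -1) for i in minima])
    kept: list[tuple[int, int]] = []
    for idx, kind in events:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            better = (v[idx] > v[prev]) if kind > 0 else (v[idx] < v[prev])
            if better:
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))
    maxima = np.array([i for i, k in kept if k > 0], int)
    minima = np.array([i for i, k in kept if k < 0], int)
    return replace(curve, maxima_idx=maxima, minima_idx=minima)


def ejection_fraction(curves: list[VolumeCurve]) -> dict:
    """EF with EDV/ESV from per-slice volume curves.

    Per slice the end-diastolic volume is the median of the detected
    maxima and the end-systolic volume the median of the minima; EDV and
    ESV sum over slices and EF = 100 * (EDV - ESV) / EDV.
    """
    edv = esv = 0.0
    per_slice = []
    for c in curves:
        if len(c.maxima_idx) == 0 or len(c.minima_idx) == 0:
            raise CurveError("each slice needs at least one maximum and minimum")
        ed = float(np.median(c.volumes_ml[c.maxima_idx]))
        es = float(np.median(c.volumes_ml[c.minima_idx]))
        per_slice.append({"ed_ml": ed, "es_ml": es,
                          "maxima_idx": c.maxima_idx.tolist(),
                          "minima_idx": c.minima_idx.tolist()})
        edv += ed
        esv += es
    if edv <= 0:
        raise CurveError("end-diastolic volume is zero")
    return {"edv_ml": edv, "esv_ml": esv,
            "ef_percent": 100.0 * (edv - esv) / edv, "slices": per_slice}


# -- generic quality metrics ----------------------------------------------

def dice(mask_a: np.ndarray, mask_b: np.ndarray, label: int = 1) -> float:
    """Dice-Sorensen overlap of one label; 1.0 when both masks are empty."""
    a = np.asarray(mask_a) == label
    b = np.asarray(mask_b) == label
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def nrmse(img: np.ndarray, ref: np.ndarray) -> float:
    """Root-mean-square error normalized by the reference value range."""
    img = np.abs(np.asarray(img, dtype=float))
    ref = np.abs(np.asarray(ref, dtype=float))
    if img.shape != ref.shape:
        raise ValueError("image shapes differ")
    rng = ref.max() - ref.min()
    if rng == 0:
        return 0.0 if np.allclose(img, ref) else np.inf
    return float(np.sqrt(np.mean((img - ref) ** 2)) / rng)


def psnr(img: np.ndarray, ref: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    img = np.abs(np.asarray(img, dtype=float))
    ref = np.abs(np.asarray(ref, dtype=float))
    mse = np.mean((img - ref) ** 2)
    if mse == 0:
        return np.inf
    peak = ref.max() - ref.min()
    return float(10 * np.log10(peak ** 2 / mse))


def ssim(img: np.ndarray, ref: np.ndarray) -> float:
    """Structural similarity index over the full reference dynamic range."""
    img = np.abs(np.asarray(img, dtype=float))
    ref = np.abs(np.asarray(ref, dtype=float))
    rng = ref.max() - ref.min()
    return float(structural_similarity(img, ref, data_range=rng if rng > 0 else 1.0))
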