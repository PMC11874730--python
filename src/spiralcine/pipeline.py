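"""End-to-end orchestration: simulate -> self-gate -> CG-SENSE -> model -> EF.

Every stage is timed and logged; all randomness derives from one root
seed through named substreams, so a run is reproducible from its config.
Frames are reconstructed individually (no temporal coupling), so frame
order never affects the result.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field

import numpy as np

from .encoding import NufftOperator, cg_sense, estimate_coils_adaptive, nufft_adjoint
from .function_metrics import detect_extrema, ejection_fraction, volume_curve
from .gating import bin_arms, detect_triggers, extract_dc
from .phantom import PhantomConfig, Session, simulate_session
from .xsdnet import XSDNet, normalize_magnitude


class StageError(RuntimeError):
    """Raised with the failing stage's name."""


@dataclass
class RunConfig:
    seed: int = 0
    mode: str = "freebreathing"
    duration_s: float = 5.7
    n_slices: int = 1
    grid: int = 64
    pixel_mm: float = 4.0
    n_coils: int = 8
    cg_iterations: int = 10
    n_phases: int = 20
    phantom_overrides: dict = field(default_factory=dict)
    checkpoint: str | None = None
    slice_scales: tuple = (1.0, 0.85, 0.65)

    def phantom_config(self, slice_index: int = 0) -> PhantomConfig:
        scale = self.slice_scales[slice_index % len(self.slice_scales)]
        ss = np.random.SeedSequence([self.seed, slice_index])
        base = dict(grid=self.grid, pixel_mm=self.pixel_mm,
                    seed=int(ss.generate_state(1)[0] % (2 ** 31)))
        base.update(self.phantom_overrides)
        cfg = PhantomConfig(**base)
        return dataclasses.replace(
            cfg,
            lv_endo_ed_mm=cfg.lv_endo_ed_mm * scale,
            lv_endo_es_mm=cfg.lv_endo_es_mm * scale,
            wall_ed_mm=cfg.wall_ed_mm * scale,
            rv_radius_mm=cfg.rv_radius_mm * scale,
            rv_offset_mm=cfg.rv_offset_mm * scale)


class StageTimer:
    def __init__(self):
        self.log: list[dict] = []

    def record(self, stage: str, seconds: float, n_items: int = 1):
        self.log.append({"stage": stage, "seconds": seconds, "n_items": n_items})


def report_timing(log: list[dict]) -> dict:
    """Per-stage mean seconds per item from a stage log."""
    out: dict[str, dict] = {}
    for entry in log:
        st = out.setdefault(entry["stage"], {"seconds": [], "items": 0})
        st["seconds"].append(entry["seconds"])
        st["items"] += entry.get("n_items", 1)
    report = {}
    for stage, st in out.items():
        total = float(np.sum(st["seconds"]))
        report[stage] = {"total_s": total,
                         "mean_s_per_item": total / max(st["items"], 1)}
    return report


def reconstruct_session(session: Session, model: XSDNet | None = None,
                        cg_iterations: int = 10, use_true_coils: bool = False,
                        timer: StageTimer | None = None,
                        frame_indices=None) -> dict:
    """Interim CG-SENSE images and (optionally) model outputs per frame."""
    timer = timer or StageTimer()
    cfg = session.config
    n = cfg.grid

    t0 = time.perf_counter()
    if use_true_coils:
        coils = session.coils
    else:
        # Walsh-style maps from the temporal average of an early segment
        na = session.base_traj.n_arms
        n_avg = min(8 * na, session.kspace.n_arms)
        import dataclasses as dc
        sub_traj = dc.replace(session.base_traj,
                              arm_coords=session.kspace.traj.arm_coords[:n_avg])
        op = NufftOperator(sub_traj, n)
        from .trajectory import density_compensation
        w = density_compensation(sub_traj)
        per_coil = np.stack([
            op.adjoint(session.kspace.samples[:n_avg, :, c].ravel() * w)
            for c in range(session.kspace.n_coils)])
        coils = estimate_coils_adaptive(per_coil)
    timer.record("coil_estimation", time.perf_counter() - t0)

    if frame_indices is None:
        frame_indices = range(session.n_frames)
    ops: dict[int, NufftOperator] = {}
    interim = []
    t0 = time.perf_counter()
    for f in frame_indices:
        bundle = session.frame_kspace(f)
        p = int(session.pattern_index[f])
        if p not in ops:
            ops[p] = NufftOperator(bundle.traj, n)
        interim.append(cg_sense(bundle, bundle.traj, coils,
                                n_iter=cg_iterations, op=ops[p]))
    interim = np.stack(interim)
    timer.record("cg_sense", time.perf_counter() - t0, len(interim))

    result = {"interim": interim, "coils": coils, "timer": timer,
              "frame_indices": np.asarray(list(frame_indices))}
    if model is not None:
        model.eval()
        t0 = time.perf_counter()
        refined, masks = [], []
        for img in interim:
            x = normalize_magnitude(img)
            out = model.forward(x[None, None])
            refined.append(out.refined.data[0, 0])
            masks.append(np.argmax(out.seg_probs.data[0], axis=0).astype(np.uint8))
        result["refined"] = np.stack(refined)
        result["masks"] = np.stack(masks)
        timer.record("model_inference", time.perf_counter() - t0, len(interim))
    return result


def run_end_to_end(config: RunConfig, model: XSDNet | None = None,
                   use_oracle_masks: bool = False) -> dict:
    """Full chain on simulated sessions; returns recon artifacts + EF report.

    One session is simulated per slice.  Masks come from the model unless
    ``use_oracle_masks`` (ground-truth labels) is requested; a model or
    checkpoint is required otherwise.
    """
    if model is None and config.checkpoint:
        model = XSDNet.load(config.checkpoint)
    if model is None and not use_oracle_masks:
        raise StageError("model: no trained checkpoint available")
    timer = StageTimer()
    curves = []
    artifacts = []
    for s in range(config.n_slices):
        pcfg = config.phantom_config(s)
        t0 = time.perf_counter()
        try:
            session = simulate_session(pcfg, mode=config.mode,
                                       duration_s=config.duration_s,
                                       n_coils=config.n_coils)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"simulate: {exc}") from exc
        timer.record("simulate", time.perf_counter() - t0, session.n_frames)

        t0 = time.perf_counter()
        try:
            sig = extract_dc(session.kspace)
            triggers = detect_triggers(sig)
            bins = bin_arms(session.kspace.arm_times, triggers,
                            n_phases=config.n_phases)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"selfgate: {exc}") from exc
        timer.record("selfgate", time.perf_counter() - t0)

        try:
            rec = reconstruct_session(session, model=model,
                                      cg_iterations=config.cg_iterations,
                                      timer=timer)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"reconstruct: {exc}") from exc

        if use_oracle_masks:
            masks = np.stack([fr.mask for fr in session.frames])
        else:
            masks = rec["masks"]
        t0 = time.perf_counter()
        try:
            curve = volume_curve(masks, session.frame_times,
                                 pcfg.pixel_area_mm2, pcfg.slice_thickness_mm)
            curve = detect_extrema(curve)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"analysis: {exc}") from exc
        timer.record("analysis", time.perf_counter() - t0)
        curves.append(curve)
        artifacts.append({"session": session, "recon": rec, "bins": bins,
                          "masks": masks, "curve": curve})

    report = ejection_fraction(curves)
    report["timing"] = report_timing(timer.log)
    return {"report": report, "slices": artifacts, "timer": timer}
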