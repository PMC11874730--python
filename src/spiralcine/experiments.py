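"""Reproducible desk-scale experiments on the synthetic phantom.

These are the standard configurations the test-suite and the worked
examples use: a 64 x 64 phantom corpus of 200 simulated training pairs
(20 virtual subjects x 10 cardiac phases, geometry and contrast jittered
per subject), CG-SENSE interim inputs from the 13-arm spiral, and a
30-epoch training run of the disentangled model.  Problem sizes are kept
at desk scale so a full run completes on a single CPU core.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .encoding import NufftOperator
from .phantom import PhantomConfig, make_set1_pair, render_frame
from .trajectory import design_spiral
from .training import TrainingConfig, TrainingSample
from .training import train as train_loop
from .xsdnet import ModelConfig, XSDNet

DESK_GRID = 64
DESK_PIXEL_MM = 4.0
DESK_N_COILS = 8
DESK_N_TRAIN = 200
DESK_N_VAL = 24
DESK_EPOCHS = 30


def desk_trajectory(grid: int = DESK_GRID, pixel_mm: float = DESK_PIXEL_MM):
    """The 13-arm variable-density spiral scaled to the desk grid."""
    return design_spiral(fov_mm=grid * pixel_mm, resolution_mm=pixel_mm,
                         n_samples=256, matrix=grid)


def sample_subject_config(rng: np.random.Generator, grid: int = DESK_GRID,
                          pixel_mm: float = DESK_PIXEL_MM) -> PhantomConfig:
    """Random anatomy/contrast variation emulating subject diversity.

    The size range spans base-to-apex short-axis geometry, so a model
    trained on this corpus sees the whole LV stack it will segment.
    """
    ed = rng.uniform(14.0, 28.0)
    ratio = rng.uniform(0.60, 0.75)
    scale = ed / 24.0
    return PhantomConfig(
        grid=grid, pixel_mm=pixel_mm,
        lv_endo_ed_mm=ed, lv_endo_es_mm=ed * ratio,
        wall_ed_mm=rng.uniform(7.0, 11.0) * np.clip(scale, 0.7, 1.1),
        rv_radius_mm=rng.uniform(18.0, 24.0) * scale,
        rv_offset_mm=rng.uniform(27.0, 32.0) * np.clip(scale, 0.75, 1.1),
        intensity_myo=rng.uniform(0.30, 0.50),
        intensity_fat=rng.uniform(0.6, 0.9),
        seed=int(rng.integers(2 ** 31)))


def make_desk_dataset(n_frames: int = DESK_N_TRAIN, seed: int = 0,
                      grid: int = DESK_GRID, pixel_mm: float = DESK_PIXEL_MM,
                      n_coils: int = DESK_N_COILS,
                      frames_per_subject: int = 10) -> list[TrainingSample]:
    """Simulated training pairs: phantom frame -> spiral raw data -> interim.

    Pattern orientation is drawn per sample from the 8-offset rotation
    schedule — deployed sessions cycle through all orientations, whose
    aliasing structures differ, so the corpus must cover them.  The CG
    step uses Walsh-estimated coils (the deployed estimation path).
    """
    from .trajectory import rotation_schedule

    rng = np.random.default_rng(seed)
    traj = desk_trajectory(grid, pixel_mm)
    offsets = rotation_schedule(8, traj.n_arms)
    ops = {}
    samples = []
    n_subjects = int(np.ceil(n_frames / frames_per_subject))
    for s in range(n_subjects):
        cfg = sample_subject_config(rng, grid, pixel_mm)
        for f in range(frames_per_subject):
            if len(samples) >= n_frames:
                break
            phase = f / frames_per_subject
            frame = render_frame(cfg, phase)
            p = int(rng.integers(len(offsets)))
            if p not in ops:
                rot = traj.rotated(offsets[p])
                ops[p] = (rot, NufftOperator(rot, grid))
            rot, op = ops[p]
            interim, target, mask = make_set1_pair(
                frame, rot, n_coils=n_coils, seed=int(rng.integers(2 ** 31)),
                op=op, estimate_maps=True)
            samples.append(TrainingSample.from_images(interim, target, mask))
    return samples


def desk_model_config(seed: int = 0) -> ModelConfig:
    return ModelConfig(base_width=12, unet_depth=2, seed=seed)


def run_desk_training(seed: int = 0, epochs: int = DESK_EPOCHS,
                      n_train: int = DESK_N_TRAIN, n_val: int = DESK_N_VAL,
                      progress: bool = False):
    """The standard desk-scale training experiment.

    Returns (model, TrainResult, val_data).  Validation subjects are
    generated from an independent seed stream, so no anatomy is shared
    with the training corpus.
    """
    train_data = make_desk_dataset(n_train, seed=seed)
    val_data = make_desk_dataset(n_val, seed=seed + 50_021, frames_per_subject=8)
    model = XSDNet(desk_model_config(seed))
    # short-budget recipe: a higher learning rate than the full-scale
    # default, appropriate for the ~750 optimizer steps of this run
    cfg = TrainingConfig(epochs=epochs, set1_per_epoch=0, batch_size=8,
                         learning_rate=1e-3, seed=seed, val_fraction=0.0)
    result = train_loop(model, cfg, train_data, set1_pool=[],
                        val_data=val_data, progress=progress)
    return model, result, val_data
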