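"""Dataset mixing, geometric augmentation, and the training loop.

Each epoch pools the whole acquired-session dataset ("set 2") with a
fresh random draw from the simulated image/mask pool ("set 1") — 282
samples per epoch at full scale — then applies random flips combined with
a right-angle rotation to every sample.  The epoch composition is a pure
function of (seed, epoch), so runs are bitwise reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .function_metrics import dice, nrmse
from .xsdnet import XSDNet, normalize_magnitude


@dataclass
class TrainingSample:
    """One (interim input, clean target, label mask) triple, all (H, W)."""

    interim: np.ndarray   # normalized magnitude input
    target: np.ndarray    # normalized magnitude target
    mask: np.ndarray      # integer labels

    @classmethod
    def from_images(cls, interim, target, mask):
        return cls(normalize_magnitude(interim), normalize_magnitude(target),
                   np.asarray(mask, dtype=np.int64))


@dataclass
class TrainingConfig:
    epochs: int = 200
    set1_per_epoch: int = 282
    batch_size: int = 8
    learning_rate: float = 1e-4
    seed: int = 0
    loss_weights: dict | None = None
    augment: bool = True
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.set1_per_epoch < 0:
            raise ValueError("set1_per_epoch must be >= 0")


def make_epoch_dataset(set2: list, set1_pool: list, n_set1: int,
                       seed: int, epoch: int) -> list:
    """All of set 2 plus ``n_set1`` drawn without replacement from set 1.

    The draw and the final shuffle are functions of (seed, epoch) only.
    """
    if n_set1 > len(set1_pool):
        raise ValueError(
            f"requested {n_set1} set-1 samples but pool has {len(set1_pool)}")
    rng = np.random.default_rng([seed, epoch])
    chosen = list(set2)
    if n_set1 > 0:
        idx = rng.choice(len(set1_pool), size=n_set1, replace=False)
        chosen.extend(set1_pool[i] for i in idx)
    order = rng.permutation(len(chosen))
    return [chosen[i] for i in order]


def augment(sample: TrainingSample, seed: int) -> TrainingSample:
    """Random horizontal/vertical flip plus rotation by 0/90/180/270 degrees.

    The same transform is applied to the interim image, the target image
    and the mask; all members of this 8-element symmetry group permute
    pixels, so label counts are preserved exactly.
    """
    rng = np.random.default_rng(seed)
    flip_h = bool(rng.integers(2))
    flip_v = bool(rng.integers(2))
    k = int(rng.integers(4))

    def tf(a):
        out = a
        if flip_h:
            out = out[:, ::-1]
        if flip_v:
            out = out[::-1, :]
        return np.ascontiguousarray(np.rot90(out, k))

    return TrainingSample(tf(sample.interim), tf(sample.target), tf(sample.mask))


@dataclass
class TrainResult:
    log: list                    # per-epoch dicts of losses and val metrics
    best_state: list             # model arrays at the best validation epoch
    best_epoch: int
    best_val: dict


class NonFiniteLossError(RuntimeError):
    pass


def _stack(batch: list[TrainingSample]):
    x = np.stack([s.interim for s in batch])[:, None].astype(np.float32)
    t = np.stack([s.target for s in batch])[:, None].astype(np.float32)
    m = np.stack([s.mask for s in batch])
    return x, t, m


def evaluate(model: XSDNet, data: list[TrainingSample]) -> dict:
    """Validation LV Dice and refined/interim NRMSE (inference mode)."""
    model.eval()
    dices, nr_ref, nr_int = [], [], []
    for s in data:
        out = model.forward(s.interim[None, None])
        pred = np.argmax(out.seg_probs.data[0], axis=0)
        dices.append(dice(pred, s.mask, label=1))
        nr_ref.append(nrmse(out.refined.data[0, 0], s.target))
        nr_int.append(nrmse(s.interim, s.target))
    model.train()
    return {"lv_dice": float(np.mean(dices)),
            "refined_nrmse": float(np.mean(nr_ref)),
            "interim_nrmse": float(np.mean(nr_int))}


def train(model: XSDNet, config: TrainingConfig, train_set2: list,
          set1_pool: list | None = None, val_data: list | None = None,
          checkpoint_path: str | None = None,
          progress: bool = False) -> TrainResult:
    """Run the training loop; keeps the best-validation checkpoint.

    ``train_set2`` and ``set1_pool`` are lists of :class:`TrainingSample`;
    ``val_data`` defaults to a held-out fraction of set 2 (split by sample
    order, which the caller should arrange to be session-contiguous so
    that no session leaks across the split).
    """
    set1_pool = set1_pool or []
    if val_data is None:
        n_val = max(int(len(train_set2) * config.val_fraction), 1)
        val_data, train_set2 = train_set2[:n_val], train_set2[n_val:]
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    log = []
    best = None
    model.train()
    for epoch in range(config.epochs):
        data = make_epoch_dataset(train_set2, set1_pool,
                                  min(config.set1_per_epoch, len(set1_pool)),
                                  config.seed, epoch)
        aug_rng = np.random.default_rng([config.seed, epoch, 104729])
        epoch_losses = []
        for b0 in range(0, len(data), config.batch_size):
            batch = data[b0:b0 + config.batch_size]
            if config.augment:
                batch = [augment(s, int(aug_rng.integers(2 ** 31)))
                         for s in batch]
            x, t, m = _stack(batch)
            out = model.forward(x)
            total, bundle = model.compute_losses(out, t, m,
                                                 weights=config.loss_weights)
            if not np.isfinite(bundle.total):
                raise NonFiniteLossError(
                    f"non-finite loss at epoch {epoch}, batch {b0 // config.batch_size}: {bundle}")
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_losses.append(bundle.as_dict())
        mean_losses = {k: float(np.mean([e[k] for e in epoch_losses]))
                       for k in epoch_losses[0]}
        val = evaluate(model, val_data)
        entry = {"epoch": epoch, **mean_losses, **val}
        log.append(entry)
        if progress:
            print(f"epoch {epoch:3d} total {mean_losses['total']:.3f} "
                  f"lv_dice {val['lv_dice']:.3f} nrmse {val['refined_nrmse']:.3f}")
        score = val["lv_dice"] - val["refined_nrmse"]
        if best is None or score > best[0]:
            best = (score, epoch, model.get_state(), val)
            if checkpoint_path:
                model.save(checkpoint_path)
    model.set_state(best[2])
    return TrainResult(log=log, best_state=best[2], best_epoch=best[1],
                       best_val=best[3])


def write_metric_log(log: list, path: str):
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(log[0].keys()))
        writer.writeheader()
        writer.writerows(log)
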