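"""Training: target preprocessing, masked MSE loss, scheduler, and the loop.

Training targets are the simulation-input maps (realized maps are kept
for evaluation).  Map values are log-transformed and each channel is
centered and scaled using training-split statistics only.  The loss is
the mean squared error over both channels of all (unmasked) grid cells.
The optimizer is Adam; the learning rate halves after every 10 epochs
without validation improvement and training stops after 100 such epochs,
restoring the best-validation weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import MapNN, PairSubsetConfig, build_locations_table, enumerate_pairs, pair_input
from .nn import Adam

__all__ = [
    "MapDataset",
    "TargetTransform",
    "TrainConfig",
    "PlateauScheduler",
    "TrainResult",
    "fit_transform",
    "masked_mse",
    "augment_resample",
    "train",
]


@dataclass
class MapDataset:
    """One training/validation example: genotypes + coordinates -> target map."""

    genotypes: np.ndarray        # (n, m) minor-allele counts (or (2n, m) phased)
    locations: np.ndarray        # (n, 2) habitat coordinates
    target: np.ndarray           # (w, w, 2) natural-scale map (sigma, K)
    mask: np.ndarray | None = None   # (w, w) booleans, True = habitable


@dataclass
class TargetTransform:
    """Per-channel log / center / scale computed on training targets."""

    center: np.ndarray   # (2,)
    scale: np.ndarray    # (2,)

    def __post_init__(self):
        if np.any(self.scale <= 0):
            raise ValueError("scale must be positive")

    def apply(self, target: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        t = np.asarray(target, dtype=float)
        sel = np.ones(t.shape[:2], dtype=bool) if mask is None else mask
        if np.any(t[sel] <= 0):
            raise ValueError("nonpositive habitable map value cannot be log-transformed")
        out = np.zeros_like(t)
        out[sel] = (np.log(t[sel]) - self.center) / self.scale
        return out

    def invert(self, transformed: np.ndarray) -> np.ndarray:
        return np.exp(np.asarray(transformed) * self.scale + self.center)

    def to_json(self) -> str:
        return json.dumps({"center": self.center.tolist(), "scale": self.scale.tolist()})

    @classmethod
    def from_json(cls, s: str) -> "TargetTransform":
        d = json.loads(s)
        return cls(np.asarray(d["center"]), np.asarray(d["scale"]))


def fit_transform(datasets: Sequence[MapDataset]) -> TargetTransform:
    """Fit the log/center/scale statistics on (habitable cells of) targets."""
    vals = []
    for d in datasets:
        sel = np.ones(d.target.shape[:2], dtype=bool) if d.mask is None else d.mask
        if np.any(d.target[sel] <= 0):
            raise ValueError("nonpositive habitable map value in training targets")
        vals.append(np.log(d.target[sel]))
    stacked = np.concatenate(vals, axis=0)   # (cells, 2)
    center = stacked.mean(axis=0)
    scale = stacked.std(axis=0)
    scale[scale == 0] = 1.0
    return TargetTransform(center, scale)


def masked_mse(Y: np.ndarray, Y_hat: np.ndarray,
               mask: np.ndarray | None = None) -> float:
    """Mean squared error over both channels of unmasked grid cells.

    Without a mask the denominator is 2 w^2; with a mask it is twice the
    number of habitable cells, so excluded cells neither penalize nor
    dilute the loss.
    """
    Y = np.asarray(Y, dtype=float)
    Y_hat = np.asarray(Y_hat, dtype=float)
    if Y.shape != Y_hat.shape:
        raise ValueError("map shapes differ")
    if mask is None:
        return float(np.mean((Y - Y_hat) ** 2))
    if not mask.any():
        raise ValueError("mask excludes every cell")
    return float(np.mean((Y[mask] - Y_hat[mask]) ** 2))


def _mse_grad(Y: np.ndarray, Y_hat: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    if mask is None:
        return 2.0 * (Y_hat - Y) / Y.size
    g = np.zeros_like(Y)
    n_entries = 2 * int(mask.sum())
    g[mask] = 2.0 * (Y_hat[mask] - Y[mask]) / n_entries
    return g


@dataclass
class TrainConfig:
    batch_size: int = 10
    learning_rate: float = 1e-4
    validation_fraction: float = 0.2
    plateau_halve: int = 10      # epochs without val improvement before lr/2
    plateau_stop: int = 100      # epochs without val improvement before stopping
    min_delta: float = 0.0       # strict reduction by default
    max_epochs: int | None = None
    checkpoint_dir: str | None = None   # save a checkpoint every epoch
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")


class PlateauScheduler:
    """Halve-on-plateau learning rate schedule with patience-based stopping.

    The first observed loss sets the baseline; an epoch counts as improved
    only when the loss drops below the best by more than ``min_delta``.
    With a frozen loss the rate halves at epochs 10, 20, ... and training
    stops at epoch 100 (with the default patience settings).
    """

    def __init__(self, lr: float, halve_after: int = 10, stop_after: int = 100,
                 min_delta: float = 0.0):
        self.lr = lr
        self.halve_after = halve_after
        self.stop_after = stop_after
        self.min_delta = min_delta
        self.best = None
        self.since_improve = 0

    def update(self, val_loss: float) -> tuple[float, bool, bool]:
        """Feed one epoch's validation loss; returns (lr, improved, stop)."""
        if self.best is None or val_loss < self.best - self.min_delta:
            improved = self.best is not None
            if self.best is None:
                self.since_improve = 1   # a baseline, not a reduction
            else:
                self.since_improve = 0
            self.best = val_loss if (self.best is None or val_loss < self.best) else self.best
            return self.lr, improved, False
        self.since_improve += 1
        if self.since_improve % self.halve_after == 0:
            self.lr /= 2.0
        return self.lr, False, self.since_improve >= self.stop_after


def augment_resample(simulations: Sequence, draws: int,
                     make_dataset: Callable[[object, np.random.Generator], MapDataset],
                     rng: np.random.Generator) -> list[MapDataset]:
    """Enlarge a simulation set by drawing several sample sets per run.

    Each simulation contributes ``draws`` independent datasets sharing the
    same target map but (with high probability) different individuals.
    """
    out = []
    for simres in simulations:
        for _ in range(draws):
            out.append(make_dataset(simres, rng))
    return out


@dataclass
class TrainResult:
    model: MapNN
    transform: TargetTransform
    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float


def _precompute_inputs(model: MapNN, datasets: Sequence[MapDataset], pairs_of: dict):
    """Pair tensors and locations tables, built once per dataset."""
    c = model.config
    dt = c.np_dtype
    px_of, lt_of = {}, {}
    for i, d in enumerate(datasets):
        pr = pairs_of[i]
        px_of[i] = pair_input(d.genotypes, pr, c.phased, c.pair_encoding).astype(dt)
        lt_of[i] = build_locations_table(d.locations, pr, c.w).reshape(
            c.w * c.w, pr.shape[0], 7).astype(dt)
    return px_of, lt_of


def train(model: MapNN, datasets: Sequence[MapDataset], config: TrainConfig,
          pair_config: PairSubsetConfig | None = None,
          transform: TargetTransform | None = None) -> TrainResult:
    """Adam training with the plateau schedule and best-weights restore.

    Pair subsets are drawn once per dataset.  The target transform is
    fitted on the training split only and applied unchanged to the
    validation split (no leakage).
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    rng = np.random.default_rng(config.seed)
    c = model.config
    if pair_config is None:
        k = min(c.n * (c.n - 1) // 2, 450)
        pair_config = PairSubsetConfig(k, min(k, 100))
    order = rng.permutation(len(datasets))
    n_val = max(1, int(round(config.validation_fraction * len(datasets))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    train_ds = [datasets[i] for i in train_idx]
    val_ds = [datasets[i] for i in val_idx]
    if transform is None:
        transform = fit_transform(train_ds)
    pairs_of = {}
    masks_of = {}
    for i, d in enumerate(datasets):
        pairs_of[i], masks_of[i] = enumerate_pairs(d.locations.shape[0], pair_config, rng)
    targets = {i: transform.apply(datasets[i].target, datasets[i].mask)
               for i in range(len(datasets))}
    px_of, lt_of = _precompute_inputs(model, datasets, pairs_of)

    sched = PlateauScheduler(config.learning_rate, config.plateau_halve,
                             config.plateau_stop, config.min_delta)
    opt = Adam(model.params, lr=config.learning_rate)
    best_weights = [p.value.copy() for p in model.params]
    best_epoch = 0
    hist = []
    epoch = 0
    while True:
        epoch += 1
        perm = rng.permutation(len(train_idx))
        train_losses = []
        for start in range(0, len(perm), config.batch_size):
            ids = [int(train_idx[j]) for j in perm[start:start + config.batch_size]]
            Y_hat = model.forward(np.stack([px_of[i] for i in ids]),
                                  np.stack([lt_of[i] for i in ids]))
            grads = np.zeros_like(Y_hat)
            losses = []
            for bi, i in enumerate(ids):
                d = datasets[i]
                losses.append(masked_mse(targets[i], Y_hat[bi], d.mask))
                grads[bi] = _mse_grad(targets[i], Y_hat[bi], d.mask) / len(ids)
            loss = float(np.mean(losses))
            if not np.isfinite(loss):
                raise FloatingPointError(f"training loss diverged at epoch {epoch}")
            train_losses.append(loss)
            opt.zero_grad()
            emask = np.stack([masks_of[i] for i in ids])
            model.backward(grads, extract_mask=emask)
            opt.step()
        val_losses = []
        for start in range(0, len(val_idx), config.batch_size):
            ids = [int(i) for i in val_idx[start:start + config.batch_size]]
            Y_hat = model.forward(np.stack([px_of[i] for i in ids]),
                                  np.stack([lt_of[i] for i in ids]))
            val_losses += [masked_mse(targets[i], Y_hat[bi], datasets[i].mask)
                           for bi, i in enumerate(ids)]
        val_loss = float(np.mean(val_losses))
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"validation loss diverged at epoch {epoch}")
        lr, improved, stop = sched.update(val_loss)
        if sched.best == val_loss and (improved or epoch == 1):
            best_weights = [p.value.copy() for p in model.params]
            best_epoch = epoch
        opt.lr = lr
        hist.append({"epoch": epoch, "train_loss": float(np.mean(train_losses)),
                     "val_loss": val_loss, "lr": lr})
        if config.checkpoint_dir is not None:
            from pathlib import Path
            ckdir = Path(config.checkpoint_dir)
            ckdir.mkdir(parents=True, exist_ok=True)
            model.save(ckdir / f"epoch{epoch:04d}.json")
        if stop or (config.max_epochs is not None and epoch >= config.max_epochs):
            break
    for p, wgt in zip(model.params, best_weights):
        p.value[...] = wgt
    return TrainResult(model, transform, pd.DataFrame(hist), best_epoch,
                       float(sched.best))
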