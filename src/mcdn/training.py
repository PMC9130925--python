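"""Supervised training of fluence denoisers on noisy/clean pairs.

Pairs couple a low-photon-count run with the highest-count run of the same
phantom/source/gate, both log-compressed at the same gain. The loss is the
mini-batch mean of element-wise |pred - clean|^n (n = 2 by default).
Augmentation applies, with probability p each, a 90-degree rotation about a
random axis and a flip along a random axis — identically to input and label.
The optimizer is Adam with decoupled weight decay (1e-4, exempting biases and
normalization parameters), linear warmup followed by cosine annealing, and
per-group gradient-norm clipping (2 for normalization parameters, 1 for the
rest). Validation global metrics (MSE, SSIM, PSNR) are logged each epoch and
the checkpoint with the best overall metrics is retained.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np

from .metrics import mse as _metric_mse
from .metrics import psnr as _metric_psnr
from .metrics import ssim3d as _metric_ssim
from .models import DenoiserModel
from .nn import AdamW, WarmupCosineSchedule, clip_gradient_groups
from .transforms import forward_log

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingPair",
    "TrainConfig",
    "History",
    "ln_loss",
    "augment_pair",
    "assemble_dataset",
    "train",
    "select_best",
]


@dataclasses.dataclass
class TrainingPair:
    """One (noisy, clean) log-volume pair from the same phantom and source."""

    noisy: np.ndarray
    clean: np.ndarray
    gain: float
    phantom_id: str = ""
    noisy_photons: int = 0
    clean_photons: int = 0

    def __post_init__(self):
        self.noisy = np.asarray(self.noisy, dtype=np.float64)
        self.clean = np.asarray(self.clean, dtype=np.float64)
        if self.noisy.shape != self.clean.shape:
            raise ValueError("noisy and clean volumes must share a shape")
        if self.noisy_photons and self.clean_photons \
                and self.clean_photons <= self.noisy_photons:
            raise ValueError("clean photon count must exceed the noisy one")


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 4
    base_lr: float = 1e-4
    weight_decay: float = 1e-4
    warmup_iters: int = 1000
    clip_norm_layers: float = 2.0
    clip_other_layers: float = 1.0
    augment_prob: float = 0.7
    loss_exponent: int = 2
    selection_metric: str = "composite"  # mse | ssim | psnr | composite
    seed: int = 0

    def __post_init__(self):
        if self.loss_exponent not in (1, 2):
            raise ValueError("loss exponent n must be 1 or 2")
        for f in ("epochs", "batch_size", "base_lr", "weight_decay",
                  "warmup_iters", "clip_norm_layers", "clip_other_layers"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if not (0 <= self.augment_prob <= 1):
            raise ValueError("augment_prob must lie in [0, 1]")


@dataclasses.dataclass
class History:
    """Per-epoch training loss and validation global metrics."""

    train_loss: list[float] = dataclasses.field(default_factory=list)
    val_mse: list[float] = dataclasses.field(default_factory=list)
    val_ssim: list[float] = dataclasses.field(default_factory=list)
    val_psnr: list[float] = dataclasses.field(default_factory=list)
    best_epoch: int | None = None

    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def ln_loss(pred: np.ndarray, target: np.ndarray, n: int = 2
            ) -> tuple[float, np.ndarray]:
    """Mini-batch mean of element-wise |pred - target|^n and its gradient."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    if n not in (1, 2):
        raise ValueError("n must be 1 or 2")
    d = pred - target
    if n == 2:
        return float(np.mean(d * d)), 2.0 * d / d.size
    return float(np.mean(np.abs(d))), np.sign(d) / d.size


_ROT_PLANES = {0: (1, 2), 1: (0, 2), 2: (0, 1)}  # rotation plane per axis


def augment_pair(pair: TrainingPair, rng: np.random.Generator, p: float = 0.7
                 ) -> TrainingPair:
    """90-degree rotation and flip, each with probability p, same for both volumes."""
    noisy, clean = pair.noisy, pair.clean
    if rng.random() < p:
        axis = int(rng.integers(3))
        plane = _ROT_PLANES[axis]
        if noisy.shape[plane[0]] != noisy.shape[plane[1]]:
            raise ValueError(
                f"90-degree rotation about axis {axis} needs a square plane; "
                f"volume shape is {noisy.shape}")
        noisy = np.rot90(noisy, axes=plane)
        clean = np.rot90(clean, axes=plane)
    if rng.random() < p:
        axis = int(rng.integers(3))
        noisy = np.flip(noisy, axis=axis)
        clean = np.flip(clean, axis=axis)
    return dataclasses.replace(pair, noisy=noisy.copy(), clean=clean.copy())


def assemble_dataset(fluence_by_domain: dict[str, dict[int, np.ndarray]],
                     photon_levels: list[int], clean_level: int,
                     gain_policy="dual", rng: np.random.Generator | None = None
                     ) -> list[TrainingPair]:
    """Build one TrainingPair per (domain, noisy level), log-compressed.

    ``fluence_by_domain`` maps domain id -> {photon_count: raw fluence array}.
    ``gain_policy``: "dual" draws c per pair uniformly from {1, 1e7} (the two
    inference gains); "loguniform" draws c per pair from the decade ladder
    {1, 10, ..., 1e7}, exposing the network to the full amplitude continuum
    between the two inference gains; a float fixes a single gain for every
    pair.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    pairs = []
    for dom in sorted(fluence_by_domain):
        vols = fluence_by_domain[dom]
        if clean_level not in vols:
            raise ValueError(f"domain {dom!r} missing clean level {clean_level}")
        for level in photon_levels:
            if level not in vols:
                raise ValueError(f"domain {dom!r} missing photon level {level}")
            if level >= clean_level:
                continue
            if gain_policy == "dual":
                gain = 1.0 if rng.random() < 0.5 else 1e7
            elif gain_policy == "loguniform":
                gain = float(10.0 ** rng.integers(0, 8))
            else:
                gain = float(gain_policy)
            pairs.append(TrainingPair(
                noisy=forward_log(vols[level], gain),
                clean=forward_log(vols[clean_level], gain),
                gain=gain,
                phantom_id=str(dom),
                noisy_photons=level,
                clean_photons=clean_level,
            ))
    return pairs


def _validate(model: DenoiserModel, val_pairs: list[TrainingPair]) -> dict:
    mses, ssims, psnrs = [], [], []
    for pair in val_pairs:
        pred = model(pair.noisy)
        mses.append(_metric_mse(pred, pair.clean))
        ssims.append(_metric_ssim(pred, pair.clean))
        p = _metric_psnr(pred, pair.clean)
        psnrs.append(p if np.isfinite(p) else 200.0)
    return {"mse": float(np.mean(mses)), "ssim": float(np.mean(ssims)),
            "psnr": float(np.mean(psnrs))}


def select_best(history: History, metric: str = "composite") -> int:
    """Index of the best epoch; ties resolved to the earliest epoch.

    ``mse`` minimizes; ``ssim``/``psnr`` maximize; ``composite`` takes the
    rank-sum over (mse down, ssim up, psnr up).
    """
    n = history.n_epochs()
    if n == 0:
        raise ValueError("history is empty")
    if metric == "mse":
        return int(np.argmin(history.val_mse))
    if metric == "ssim":
        return int(np.argmax(history.val_ssim))
    if metric == "psnr":
        return int(np.argmax(history.val_psnr))
    if metric != "composite":
        raise ValueError(f"unknown selection metric {metric!r}")

    def ranks(values, descending):
        order = np.argsort([-v if descending else v for v in values],
                           kind="stable")
        r = np.empty(len(values), dtype=int)
        r[order] = np.arange(len(values))
        return r

    total = (ranks(history.val_mse, descending=False)
             + ranks(history.val_ssim, descending=True)
             + ranks(history.val_psnr, descending=True))
    return int(np.argmin(total))  # argmin returns the earliest on ties


def train(model: DenoiserModel, dataset: list[TrainingPair],
          val_dataset: list[TrainingPair], config: TrainConfig,
          checkpoint_dir=None) -> tuple[DenoiserModel, History]:
    """Train a denoiser; returns the model restored to its best epoch.

    Every source of randomness (shuffling, augmentation) derives from
    ``config.seed``; identical config and data give identical history.
    """
    from .models import load_checkpoint, save_checkpoint
    import tempfile

    if not dataset or not val_dataset:
        raise ValueError("datasets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = AdamW(model.params(), lr=config.base_lr,
                weight_decay=config.weight_decay)
    iters_per_epoch = int(np.ceil(len(dataset) / config.batch_size))
    total_iters = max(config.epochs * iters_per_epoch, config.warmup_iters + 1)
    sched = WarmupCosineSchedule(config.base_lr, config.warmup_iters, total_iters)
    history = History()
    own_dir = checkpoint_dir is None
    ckpt_dir = Path(tempfile.mkdtemp(prefix="mcdn_ckpt_")) if own_dir \
        else Path(checkpoint_dir)
    ckpt_dir.mkdir(parents=True, exist_ok=True)
    iteration = 0
    best_path = None
    # batches are gain-homogeneous: normalization statistics are meaningless
    # across the hugely different scales of c=1 and c=1e7 log volumes
    by_gain: dict[float, list[int]] = {}
    for i, pair in enumerate(dataset):
        by_gain.setdefault(pair.gain, []).append(i)
    for epoch in range(config.epochs):
        batches = []
        for idxs in by_gain.values():
            perm = rng.permutation(len(idxs))
            for start in range(0, len(perm), config.batch_size):
                batches.append([idxs[j] for j in perm[start:start + config.batch_size]])
        batch_order = rng.permutation(len(batches))
        losses = []
        for b in batch_order:
            batch_idx = batches[b]
            vols = [augment_pair(dataset[i], rng, config.augment_prob)
                    for i in batch_idx]
            x = np.stack([v.noisy for v in vols])[:, None]
            t = np.stack([v.clean for v in vols])[:, None]
            opt.zero_grad()
            pred = model.forward_batch(x, training=True)
            loss, dloss = ln_loss(pred, t, config.loss_exponent)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}, "
                    f"iteration {iteration}")
            model.backward(dloss)
            clip_gradient_groups(model.params(), config.clip_norm_layers,
                                 config.clip_other_layers)
            opt.step(lr=sched.lr(iteration))
            iteration += 1
            losses.append(loss)
        history.train_loss.append(float(np.mean(losses)))
        val = _validate(model, val_dataset)
        history.val_mse.append(val["mse"])
        history.val_ssim.append(val["ssim"])
        history.val_psnr.append(val["psnr"])
        save_checkpoint(model, ckpt_dir / f"epoch_{epoch:04d}.npz")
        logger.info("epoch %d: loss=%.5g val_mse=%.5g val_ssim=%.4f val_psnr=%.2f",
                    epoch, history.train_loss[-1], val["mse"], val["ssim"],
                    val["psnr"])
    best = select_best(history, config.selection_metric)
    history.best_epoch = best
    best_path = ckpt_dir / f"epoch_{best:04d}.npz"
    best_model = load_checkpoint(best_path)
    best_model.metadata.update({
        "best_epoch": best,
        "epochs": config.epochs,
        "selection_metric": config.selection_metric,
        "gains": sorted({p.gain for p in dataset}),
    })
    if own_dir:
        import shutil
        shutil.rmtree(ckpt_dir, ignore_errors=True)
    return best_model, history
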