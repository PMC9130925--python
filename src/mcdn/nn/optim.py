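"""Optimization: AdamW with parameter groups, clipping, warmup-cosine schedule.

Weight decay is decoupled (applied directly to the parameter value, not through
the gradient) and exempts biases and normalization parameters. Gradient
clipping rescales each group's global gradient norm: normalization parameters
are clipped at one value (default 2), everything else at another (default 1).
"""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["AdamW", "WarmupCosineSchedule", "clip_gradient_groups"]


def clip_gradient_groups(params: list[Param], clip_norm: float = 2.0,
                         clip_other: float = 1.0) -> dict[str, float]:
    """Rescale gradients so each group's global L2 norm is within its clip value.

    Returns the pre-clip norms per group (for logging/divergence checks).
    """
    groups = {
        "norm": [p for p in params if p.kind == "norm"],
        "other": [p for p in params if p.kind != "norm"],
    }
    clips = {"norm": clip_norm, "other": clip_other}
    norms = {}
    for key, group in groups.items():
        if not group:
            continue
        total = np.sqrt(sum(float(np.sum(p.grad ** 2)) for p in group))
        norms[key] = total
        if total > clips[key] > 0:
            scale = clips[key] / total
            for p in group:
                p.grad *= scale
    return norms


class WarmupCosineSchedule:
    """Linear warmup to the base rate, then cosine annealing to zero."""

    def __init__(self, base_lr: float, warmup_iters: int, total_iters: int):
        if total_iters <= warmup_iters:
            raise ValueError("total_iters must exceed warmup_iters")
        self.base_lr = base_lr
        self.warmup_iters = warmup_iters
        self.total_iters = total_iters

    def lr(self, iteration: int) -> float:
        if iteration < self.warmup_iters:
            return self.base_lr * iteration / self.warmup_iters
        frac = (iteration - self.warmup_iters) / (self.total_iters - self.warmup_iters)
        frac = min(frac, 1.0)
        return self.base_lr * 0.5 * (1.0 + np.cos(np.pi * frac))


class AdamW:
    """Adam with decoupled weight decay; decay skips bias and norm params."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    @property
    def decayed_params(self) -> list[Param]:
        """Parameters subject to weight decay (weights only, never bias/norm)."""
        return [p for p in self.params if p.kind == "weight"]

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m += (1.0 - self.beta1) * (p.grad - m)
            v += (1.0 - self.beta2) * (p.grad ** 2 - v)
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if p.kind == "weight" and self.weight_decay:
                p.value -= lr * self.weight_decay * p.value
            p.value -= lr * update

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
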