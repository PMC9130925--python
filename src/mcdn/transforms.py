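"""Dynamic-range compression of fluence volumes and dual-gain inference.

MC fluence spans many decades; the denoisers work on the compressed
representation ``y = ln(c * x + 1)`` with a user gain ``c`` (the +1 keeps the
output non-negative), inverted by ``x = (exp(y) - 1) / c``. Because CNN
denoising quality degrades for raw fluence below an empirical threshold of
0.03, inference runs twice — once at a low gain (c = 1) and once at a high
gain (c = 1e7) — and merges voxel-wise: voxels whose *original* fluence
exceeds the threshold take the low-gain result, the rest the high-gain one.

All transforms are evaluated in double precision: at c = 1e7 a
single-precision log/exp round trip loses significant digits.
Volumes are deliberately never normalized by their maximum.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["MergePolicy", "forward_log", "inverse_log", "dual_gain_denoise"]


@dataclasses.dataclass(frozen=True)
class MergePolicy:
    """Dual-gain merge rule: threshold on raw fluence, two gains c1 < c2."""

    threshold: float = 0.03
    low_gain: float = 1.0
    high_gain: float = 1e7

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not (self.high_gain > self.low_gain > 0):
            raise ValueError("gains must satisfy high_gain > low_gain > 0")


def forward_log(x: np.ndarray, c: float) -> np.ndarray:
    """Compress fluence: ``y = ln(c * x + 1)`` element-wise, double precision."""
    if c <= 0:
        raise ValueError("gain c must be positive")
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        idx = tuple(int(i) for i in np.unravel_index(int(np.argmin(x)), x.shape))
        raise ValueError(f"negative fluence at voxel {idx}: {x[idx]}")
    return np.log1p(c * x)


def inverse_log(y: np.ndarray, c: float) -> np.ndarray:
    """Invert the compression: ``x = (exp(y) - 1) / c``.

    Slightly negative inputs (denoiser overshoot) are clamped to zero with a
    logged warning.
    """
    if c <= 0:
        raise ValueError("gain c must be positive")
    y = np.asarray(y, dtype=np.float64)
    if np.any(y < 0):
        n_neg = int(np.sum(y < 0))
        logger.warning("clamping %d negative log-space voxels to 0 before inversion",
                       n_neg)
        y = np.maximum(y, 0.0)
    return np.expm1(y) / c


def dual_gain_denoise(x: np.ndarray, model, policy: MergePolicy = MergePolicy()
                      ) -> np.ndarray:
    """Denoise a raw fluence volume with two gains and merge by threshold.

    ``model`` is any callable mapping a log-space volume to a log-space volume
    of the same shape (e.g. :class:`mcdn.models.DenoiserModel`). The returned
    volume is non-negative, and every voxel comes from exactly one of the two
    passes, routed on the original noisy input.
    """
    x = np.asarray(x, dtype=np.float64)
    out_low = inverse_log(np.asarray(model(forward_log(x, policy.low_gain))),
                          policy.low_gain)
    out_high = inverse_log(np.asarray(model(forward_log(x, policy.high_gain))),
                           policy.high_gain)
    if out_low.shape != x.shape or out_high.shape != x.shape:
        raise ValueError(
            f"model changed volume shape: {x.shape} -> {out_low.shape}/{out_high.shape}")
    return np.where(x > policy.threshold, out_low, out_high)
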