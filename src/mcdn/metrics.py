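"""Global and local denoising quality metrics for 3D fluence volumes.

Global metrics (computed on log-compressed volumes): mean squared / absolute
error, 3D SSIM with Gaussian-weighted local statistics (sigma = 5 voxels by
default), and PSNR defined as ``20 log10(Imax / RMSE)`` with Imax = 40, the
ceiling of the log-compressed dynamic range.

Local metrics come from a stack of independently seeded repetitions: the
voxel-wise SNR ``20 log10(mu / sigma)`` in dB, the mean SNR improvement
delta-SNR (over all mutually valid voxels, and over the "effective" region
improved by more than 0.5 dB), and the photon multiplier
``MF = 10^(delta-SNR / 10)`` — the factor by which the photon count would
have to grow to match the denoiser's SNR gain.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "SSIMParams",
    "PSNRParams",
    "SNRMap",
    "MetricsReport",
    "mse",
    "mae",
    "ssim3d",
    "psnr",
    "snr_map",
    "delta_snr",
    "photon_multiplier",
    "cross_section_profile",
    "make_report",
]

DEFAULT_IMAX = 40.0
DEFAULT_EFF_THRESHOLD_DB = 0.5


@dataclasses.dataclass(frozen=True)
class SSIMParams:
    """Gaussian window width and stabilizing constants for 3D SSIM."""

    gaussian_sigma: float = 5.0
    data_range: float = DEFAULT_IMAX
    k1: float = 0.01
    k2: float = 0.03
    truncate: float = 3.0  # kernel radius in sigmas

    def __post_init__(self):
        if self.gaussian_sigma <= 0 or self.data_range <= 0:
            raise ValueError("gaussian_sigma and data_range must be positive")

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2


@dataclasses.dataclass(frozen=True)
class PSNRParams:
    i_max: float = DEFAULT_IMAX

    def __post_init__(self):
        if self.i_max <= 0:
            raise ValueError("i_max must be positive")


@dataclasses.dataclass
class SNRMap:
    """Voxel-wise SNR (dB) from a repetition stack, with a validity mask."""

    values: np.ndarray  # dB; meaningful only where valid
    valid: np.ndarray  # bool: mu > 0 and sigma > 0
    n_reps: int
    photon_count: int = 0


@dataclasses.dataclass
class MetricsReport:
    """Bundle of global + local metrics for one (volume, denoiser) evaluation."""

    mse: float
    ssim: float
    psnr: float
    delta_snr_all: float
    delta_snr_eff: float
    mf: float
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if np.isfinite(self.delta_snr_all):
            expected = photon_multiplier(self.delta_snr_all)
            if abs(self.mf - expected) > 1e-9 * max(1.0, abs(expected)):
                raise ValueError("mf inconsistent with delta_snr_all")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _check_shapes(x, y):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def mse(x, y) -> float:
    x, y = _check_shapes(x, y)
    return float(np.mean((x - y) ** 2))


def mae(x, y) -> float:
    x, y = _check_shapes(x, y)
    return float(np.mean(np.abs(x - y)))


def ssim3d(x, y, params: SSIMParams = SSIMParams()) -> float:
    """Mean structural similarity with 3D Gaussian-weighted local statistics.

    Local means, variances and covariance are obtained by convolving with an
    isotropic Gaussian (sigma in voxels, truncated at ``truncate`` sigmas,
    reflective borders); the per-voxel SSIM map is averaged over the volume.
    Identical volumes give exactly 1.
    """
    x, y = _check_shapes(x, y)

    def g(a):
        return ndimage.gaussian_filter(a, params.gaussian_sigma,
                                       mode="reflect", truncate=params.truncate)

    ux, uy = g(x), g(y)
    vx = g(x * x) - ux * ux
    vy = g(y * y) - uy * uy
    cov = g(x * y) - ux * uy
    c1, c2 = params.c1, params.c2
    ssim_map = ((2 * ux * uy + c1) * (2 * cov + c2)) \
        / ((ux * ux + uy * uy + c1) * (vx + vy + c2))
    return float(np.mean(ssim_map))


def psnr(x, y, params: PSNRParams = PSNRParams()) -> float:
    """Peak SNR in dB: ``20 log10(i_max / RMSE)``; +inf for identical volumes."""
    m = mse(x, y)
    if m == 0.0:
        return float("inf")
    return float(20.0 * np.log10(params.i_max) - 10.0 * np.log10(m))


def snr_map(stack, photon_count: int = 0) -> SNRMap:
    """Voxel-wise SNR from >= 2 repetitions (population standard deviation)."""
    arrs = [np.asarray(getattr(v, "values", v), dtype=np.float64) for v in stack]
    if len(arrs) < 2:
        raise ValueError("need at least 2 repetitions")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("repetition volumes must share a shape")
    data = np.stack(arrs)
    mu = data.mean(axis=0)
    sigma = data.std(axis=0)  # population (1/N) estimator
    valid = (mu > 0) & (sigma > 0)
    values = np.full(shape, np.nan)
    values[valid] = 20.0 * np.log10(mu[valid] / sigma[valid])
    return SNRMap(values=values, valid=valid, n_reps=len(arrs),
                  photon_count=photon_count)


def delta_snr(before: SNRMap, after: SNRMap,
              eff_threshold_db: float = DEFAULT_EFF_THRESHOLD_DB,
              region: np.ndarray | None = None) -> tuple[float, float]:
    """Mean SNR improvement (dB) over mutually valid voxels.

    Returns ``(delta_all, delta_eff)``: the mean difference over all voxels
    valid in both maps (optionally intersected with a region mask), and the
    same mean restricted to voxels improved by more than ``eff_threshold_db``
    (NaN when no voxel qualifies).
    """
    if before.values.shape != after.values.shape:
        raise ValueError("SNR maps must share a shape")
    mask = before.valid & after.valid
    if region is not None:
        mask &= np.asarray(region, dtype=bool)
    if not mask.any():
        raise ValueError("no commonly valid voxels")
    diff = after.values[mask] - before.values[mask]
    delta_all = float(np.mean(diff))
    eff = diff[diff > eff_threshold_db]
    delta_eff = float(np.mean(eff)) if eff.size else float("nan")
    return delta_all, delta_eff


def photon_multiplier(delta_snr_db: float) -> float:
    """Equivalent photon-count multiplier ``MF = 10^(delta_snr / 10)``."""
    if not np.isfinite(delta_snr_db):
        raise ValueError("delta SNR must be finite")
    return float(10.0 ** (delta_snr_db / 10.0))


def cross_section_profile(stack, line_axis: int = 0,
                          fixed_indices: tuple[int, int] | None = None):
    """Mean and SNR along an axis-aligned line through a repetition stack.

    ``fixed_indices`` pins the two non-free axes (defaults to the volume
    center, the analogue of profiling along x = y = center). Returns a dict of
    1D arrays: position (voxels), mean fluence, SNR (dB, NaN where invalid).
    """
    arrs = [np.asarray(getattr(v, "values", v), dtype=np.float64) for v in stack]
    shape = arrs[0].shape
    if line_axis not in (0, 1, 2):
        raise ValueError("line_axis must be 0, 1 or 2")
    other = [a for a in range(3) if a != line_axis]
    if fixed_indices is None:
        fixed_indices = (shape[other[0]] // 2, shape[other[1]] // 2)
    for a, idx in zip(other, fixed_indices):
        if not (0 <= idx < shape[a]):
            raise ValueError(f"line index {idx} outside axis {a} "
                             f"(size {shape[a]})")
    sel = [slice(None)] * 3
    sel[other[0]] = fixed_indices[0]
    sel[other[1]] = fixed_indices[1]
    sel = tuple(sel)
    smap = snr_map(arrs)
    data = np.stack(arrs)
    mean_line = data.mean(axis=0)[sel]
    snr_line = smap.values[sel]
    return {
        "position": np.arange(shape[line_axis]),
        "mean": mean_line,
        "snr_db": snr_line,
    }


def profile_to_csv(profile: dict, path) -> None:
    from pathlib import Path

    rows = ["position,mean,snr_db"]
    for p, m, s in zip(profile["position"], profile["mean"], profile["snr_db"]):
        rows.append(f"{p},{m!r},{s!r}")
    Path(path).write_text("\n".join(rows) + "\n")


def make_report(clean_log: np.ndarray, denoised_log: np.ndarray,
                before: SNRMap, after: SNRMap, metadata: dict | None = None
                ) -> MetricsReport:
    """Assemble global metrics (log space) + local metrics into one report."""
    d_all, d_eff = delta_snr(before, after)
    return MetricsReport(
        mse=mse(denoised_log, clean_log),
        ssim=ssim3d(denoised_log, clean_log),
        psnr=psnr(denoised_log, clean_log),
        delta_snr_all=d_all,
        delta_snr_eff=d_eff,
        mf=photon_multiplier(d_all),
        metadata=metadata or {},
    )
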