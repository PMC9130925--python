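"""Residual 3D denoising networks: DnCNN-style, UNet-style, and their cascade.

All networks operate on log-compressed fluence volumes and learn in the
residual space: the body predicts a noise map ``r`` and the output is
``y - r``. The cascade chains a global stage (plain deep conv stack, good at
spatially invariant noise) with a local stage (encoder-decoder with skip
connections, good at spatially varying noise); the second stage denoises the
first stage's output, so with both residual heads zeroed the whole cascade is
an exact pass-through.

Inference accepts any 3D volume: inputs are edge-padded to the network's
stride multiple and cropped back, so output shape always equals input shape.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .nn import (
    AvgPool3d,
    BatchNorm3d,
    Conv3d,
    ConvBlock,
    ConvTranspose3d,
    Param,
    ReLU,
    Sequential,
)

__all__ = [
    "GlobalStageSpec",
    "LocalStageSpec",
    "DnCNN3d",
    "UNet3d",
    "CascadeDenoiser",
    "DenoiserModel",
    "build_dncnn3d",
    "build_unet3d",
    "build_cascade",
    "denoise_volume",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclasses.dataclass(frozen=True)
class GlobalStageSpec:
    """DnCNN-style stage: ``depth`` conv blocks of ``width`` channels."""

    depth: int = 8
    width: int = 32
    kernel_size: int = 3

    def __post_init__(self):
        if self.depth < 3:
            raise ValueError("global stage depth must be >= 3")
        if self.width < 8:
            raise ValueError("global stage width must be >= 8")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")


@dataclasses.dataclass(frozen=True)
class LocalStageSpec:
    """UNet-style stage: ``n_scales`` resolution levels, ``base_width`` channels."""

    n_scales: int = 3
    base_width: int = 16

    def __post_init__(self):
        if self.n_scales < 2:
            raise ValueError("local stage needs at least 2 scales")
        if self.base_width < 1:
            raise ValueError("base_width must be positive")


class _ResidualNet:
    """Common surface for the residual denoisers below."""

    stride_multiple: int = 1

    def params(self) -> list[Param]:
        raise NotImplementedError

    def batchnorms(self) -> list[BatchNorm3d]:
        raise NotImplementedError

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_residual_head(self) -> None:
        raise NotImplementedError


def _collect_bns(seq: Sequential) -> list[BatchNorm3d]:
    out = []
    for layer in seq.layers:
        if isinstance(layer, Sequential):
            out.extend(_collect_bns(layer))
        elif isinstance(layer, BatchNorm3d):
            out.append(layer)
    return out


class DnCNN3d(_ResidualNet):
    """Plain deep 3D conv stack predicting a global noise residual."""

    def __init__(self, spec: GlobalStageSpec, rng: np.random.Generator):
        self.spec = spec
        k = spec.kernel_size
        layers = [Conv3d(1, spec.width, k, rng=rng, name="g.in"), ReLU()]
        for i in range(spec.depth - 2):
            layers.append(ConvBlock(spec.width, spec.width, k, rng=rng,
                                    name=f"g.b{i}"))
        self.head = Conv3d(spec.width, 1, k, rng=rng, name="g.head")
        self.head.zero_init()  # start as an exact identity map
        layers.append(self.head)
        self.body = Sequential(*layers)

    def params(self):
        return self.body.params()

    def batchnorms(self):
        return _collect_bns(self.body)

    def zero_residual_head(self):
        self.head.zero_init()

    def forward(self, x, training=False):
        r = self.body.forward(x, training=training)
        return x - r

    def backward(self, dout):
        return dout + self.body.backward(-dout)


class UNet3d(_ResidualNet):
    """3D encoder-decoder with skip connections predicting a local residual.

    Batch normalization sits between the convolution, transposed-convolution
    and pooling layers; downsampling is 2x average pooling and upsampling a
    2x transposed convolution.
    """

    def __init__(self, spec: LocalStageSpec, rng: np.random.Generator):
        self.spec = spec
        S = spec.n_scales
        w = spec.base_width
        self.stride_multiple = 2 ** (S - 1)
        self.enc = []
        c_in = 1
        for s in range(S - 1):
            c = w * 2 ** s
            self.enc.append(Sequential(
                ConvBlock(c_in, c, rng=rng, name=f"l.enc{s}a"),
                ConvBlock(c, c, rng=rng, name=f"l.enc{s}b"),
            ))
            c_in = c
        self.pools = [AvgPool3d() for _ in range(S - 1)]
        cb = w * 2 ** (S - 1)
        self.bottleneck = Sequential(
            ConvBlock(c_in, cb, rng=rng, name="l.bota"),
            ConvBlock(cb, cb, rng=rng, name="l.botb"),
        )
        self.up = []
        self.dec = []
        for s in reversed(range(S - 1)):
            c = w * 2 ** s
            self.up.append(Sequential(
                ConvTranspose3d(c * 2, c, rng=rng, name=f"l.up{s}"),
                BatchNorm3d(c, name=f"l.upbn{s}"),
                ReLU(),
            ))
            self.dec.append(Sequential(
                ConvBlock(2 * c, c, rng=rng, name=f"l.dec{s}a"),
                ConvBlock(c, c, rng=rng, name=f"l.dec{s}b"),
            ))
        self.head = Conv3d(w, 1, 3, rng=rng, name="l.head")
        self.head.zero_init()  # start as an exact identity map

    def _modules(self):
        return self.enc + self.up + self.dec + [self.bottleneck, self.head]

    def params(self):
        return [p for m in self._modules() for p in m.params()]

    def batchnorms(self):
        out = []
        for m in self._modules():
            if isinstance(m, Sequential):
                out.extend(_collect_bns(m))
        return out

    def zero_residual_head(self):
        self.head.zero_init()

    def forward(self, x, training=False):
        S = self.spec.n_scales
        h = x
        skips = []
        for s in range(S - 1):
            h = self.enc[s].forward(h, training=training)
            skips.append(h)
            h = self.pools[s].forward(h, training=training)
        h = self.bottleneck.forward(h, training=training)
        for i, s in enumerate(reversed(range(S - 1))):
            h = self.up[i].forward(h, training=training)
            h = np.concatenate([h, skips[s]], axis=1)
            h = self.dec[i].forward(h, training=training)
        r = self.head.forward(x=h, training=training)
        return x - r

    def backward(self, dout):
        S = self.spec.n_scales
        w = self.spec.base_width
        dh = self.head.backward(-dout)
        dskips = [None] * (S - 1)
        # decoder backward: reverse of forward order (forward ran i = 0..S-2,
        # touching scales s = S-2..0)
        for i in reversed(range(S - 1)):
            s = (S - 2) - i
            c = w * 2 ** s
            dh = self.dec[i].backward(dh)
            d_up, d_skip = dh[:, :c], dh[:, c:]
            dskips[s] = d_skip
            dh = self.up[i].backward(np.ascontiguousarray(d_up))
        dh = self.bottleneck.backward(dh)
        for s in reversed(range(S - 1)):
            dh = self.pools[s].backward(dh)
            dh = dh + dskips[s]
            dh = self.enc[s].backward(dh)
        return dout + dh


class CascadeDenoiser(_ResidualNet):
    """Global stage followed by a local stage, both residual; trained jointly."""

    def __init__(self, global_spec: GlobalStageSpec, local_spec: LocalStageSpec,
                 rng: np.random.Generator):
        self.global_stage = DnCNN3d(global_spec, rng)
        self.local_stage = UNet3d(local_spec, rng)
        self.stride_multiple = self.local_stage.stride_multiple

    def params(self):
        return self.global_stage.params() + self.local_stage.params()

    def batchnorms(self):
        return self.global_stage.batchnorms() + self.local_stage.batchnorms()

    def zero_residual_head(self):
        self.global_stage.zero_residual_head()
        self.local_stage.zero_residual_head()

    def forward(self, x, training=False):
        h = self.global_stage.forward(x, training=training)
        return self.local_stage.forward(h, training=training)

    def backward(self, dout):
        dh = self.local_stage.backward(dout)
        return self.global_stage.backward(dh)


@dataclasses.dataclass
class DenoiserModel:
    """An architecture + parameters, callable on arbitrary 3D log volumes."""

    architecture: str  # "dncnn" | "unet" | "cascade"
    net: _ResidualNet
    global_spec: GlobalStageSpec | None = None
    local_spec: LocalStageSpec | None = None
    metadata: dict = dataclasses.field(default_factory=dict)

    def params(self):
        return self.net.params()

    def zero_residual_head(self):
        self.net.zero_residual_head()

    def forward_batch(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Training-path forward on an NCDHW batch (shape must already fit)."""
        return self.net.forward(x, training=training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)

    def __call__(self, volume: np.ndarray) -> np.ndarray:
        """Inference on a single 3D volume with pad-to-stride and crop."""
        volume = np.asarray(volume, dtype=np.float64)
        if volume.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {volume.shape}")
        if not np.all(np.isfinite(volume)):
            idx = tuple(int(i) for i in np.unravel_index(
                int(np.argmin(np.isfinite(volume))), volume.shape))
            raise ValueError(f"non-finite voxel at index {idx}")
        m = self.net.stride_multiple
        shape = np.array(volume.shape)
        padded = (-shape) % m
        x = np.pad(volume, [(0, int(p)) for p in padded], mode="edge")
        out = self.net.forward(x[None, None], training=False)[0, 0]
        return out[: shape[0], : shape[1], : shape[2]]


def build_dncnn3d(spec: GlobalStageSpec = GlobalStageSpec(), seed: int = 0
                  ) -> DenoiserModel:
    rng = np.random.default_rng(seed)
    return DenoiserModel("dncnn", DnCNN3d(spec, rng), global_spec=spec)


def build_unet3d(spec: LocalStageSpec = LocalStageSpec(), seed: int = 0
                 ) -> DenoiserModel:
    rng = np.random.default_rng(seed)
    return DenoiserModel("unet", UNet3d(spec, rng), local_spec=spec)


def build_cascade(global_spec: GlobalStageSpec = GlobalStageSpec(),
                  local_spec: LocalStageSpec = LocalStageSpec(),
                  seed: int = 0) -> DenoiserModel:
    rng = np.random.default_rng(seed)
    return DenoiserModel("cascade", CascadeDenoiser(global_spec, local_spec, rng),
                         global_spec=global_spec, local_spec=local_spec)


def denoise_volume(model: DenoiserModel, y: np.ndarray,
                   tiling: str | tuple[int, int] = "whole") -> np.ndarray:
    """Apply a denoiser to a 3D log volume, whole or tile-by-tile.

    ``tiling`` is ``"whole"`` (the reference path) or ``(patch_size,
    overlap)``: the volume is split into disjoint cores of side
    ``patch_size - 2 * overlap``; each core is processed together with a halo
    of ``overlap`` voxels of true neighboring data and the halo is discarded.
    Wherever the halo covers the network's receptive field the patched output
    equals the whole-volume output exactly, so patch mode bounds memory at
    negligible accuracy cost.
    """
    y = np.asarray(y, dtype=np.float64)
    if tiling == "whole":
        return model(y)
    size, overlap = tiling
    m = model.net.stride_multiple
    if size % m != 0:
        raise ValueError(f"patch size {size} must be a multiple of the model "
                         f"stride {m}")
    core = size - 2 * overlap
    if core < 1:
        raise ValueError(f"patch size {size} too small for halo {overlap}")
    out = np.empty_like(y)
    starts = [list(range(0, s, core)) for s in y.shape]
    for c0i in starts[0]:
        for c0j in starts[1]:
            for c0k in starts[2]:
                c1 = (min(c0i + core, y.shape[0]),
                      min(c0j + core, y.shape[1]),
                      min(c0k + core, y.shape[2]))
                lo = (max(0, c0i - overlap), max(0, c0j - overlap),
                      max(0, c0k - overlap))
                hi = (min(y.shape[0], c1[0] + overlap),
                      min(y.shape[1], c1[1] + overlap),
                      min(y.shape[2], c1[2] + overlap))
                patch = y[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
                res = model(patch)
                out[c0i:c1[0], c0j:c1[1], c0k:c1[2]] = res[
                    c0i - lo[0]:c1[0] - lo[0],
                    c0j - lo[1]:c1[1] - lo[1],
                    c0k - lo[2]:c1[2] - lo[2]]
    return out


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: DenoiserModel, path) -> None:
    """Single-file archive: architecture spec JSON + all tensors (params + BN stats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    spec = {
        "architecture": model.architecture,
        "global_spec": dataclasses.asdict(model.global_spec) if model.global_spec else None,
        "local_spec": dataclasses.asdict(model.local_spec) if model.local_spec else None,
        "metadata": model.metadata,
    }
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    for i, bn in enumerate(model.net.batchnorms()):
        arrays[f"bn_mean_{i}"] = bn.running_mean
        arrays[f"bn_var_{i}"] = bn.running_var
    np.savez(path, _spec=json.dumps(spec), **arrays)


def load_checkpoint(path) -> DenoiserModel:
    """Rebuild a model from its architecture name + spec, then load tensors."""
    with np.load(Path(path), allow_pickle=False) as data:
        spec = json.loads(str(data["_spec"]))
        arch = spec["architecture"]
        gspec = GlobalStageSpec(**spec["global_spec"]) if spec["global_spec"] else None
        lspec = LocalStageSpec(**spec["local_spec"]) if spec["local_spec"] else None
        if arch == "dncnn":
            model = build_dncnn3d(gspec)
        elif arch == "unet":
            model = build_unet3d(lspec)
        elif arch == "cascade":
            model = build_cascade(gspec, lspec)
        else:
            raise ValueError(f"unknown architecture {arch!r}")
        model.metadata = spec.get("metadata", {})
        for i, p in enumerate(model.params()):
            arr = data[f"param_{i}"]
            if arr.shape != p.value.shape:
                raise ValueError("checkpoint does not match architecture spec")
            p.value[...] = arr
        for i, bn in enumerate(model.net.batchnorms()):
            bn.running_mean[...] = data[f"bn_mean_{i}"]
            bn.running_var[...] = data[f"bn_var_{i}"]
    return model
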