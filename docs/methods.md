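# Methods

This note documents the models, numerical choices and desk-scale study
conditions implemented in `mcdn`, and what the test suite does and does not
demonstrate.

## Problem setting

Monte Carlo (MC) photon transport is the reference method for modeling light
propagation in turbid media such as tissue, but its output fluence maps carry
shot noise: the voxel-wise signal-to-noise ratio (SNR) grows roughly 10 dB
per tenfold increase in simulated photons. `mcdn` implements a denoising
pipeline that trades a learned prior for photons: a cascaded residual 3D CNN
is trained on pairs of low-photon ("noisy") and high-photon ("clean")
simulations of randomly generated phantoms, and its SNR gain is read as an
equivalent photon multiplier `MF = 10^(dSNR/10)`.

## Phantom generation

Random domains are built from M ~ U{0..4} inclusions — convex polyhedra
(convex hulls of N ~ U{4..10} points sampled uniformly on a random sphere)
and extruded ASCII glyphs (rendered from a TrueType font, thresholded at 50%
pixel coverage, stacked to a random thickness) — rigidly rotated (uniform
over SO(3) via random unit quaternions) and placed in a homogeneous
background. Each inclusion mask enters the label volume with a power-of-two
coefficient, so every overlap pattern accumulates to a unique label and
overlapping regions become new inclusions of their own.

Per-label optical properties: `mua = |N(0.01, 0.05)|` mm^-1,
`g ~ U[0.9, 1)`, `mus = mus'/(1-g)` with `mus' = |N(1, 1)|` mm^-1, and
`n ~ U[1, 10]`. The refractive-index range is far wider than physiological
tissue (n ~ 1.33-1.5); it is kept as the generator default because it is the
stated study condition, with an `n_range` override for physiological use.
A voxel belongs to a shape iff its center (at `(i + 0.5) * voxel_size`) is
inside the shape; masks are binarized with nearest-neighbor resampling after
rigid motion. Glyph strokes thinner than one voxel keep their peak-coverage
pixels so small font sizes cannot produce empty inclusions.

## Photon transport

The forward solver is a voxelated photon-packet random walk: exponential
step sampling against the local `mus`, Henyey-Greenstein scattering
(inverse-CDF sampling; the sample mean of the deflection cosine equals `g`),
and continuous absorption weighting `w *= exp(-mua * l)` per segment.
Fluence is scored as deposited energy `/(mua * V * N)`, with the equivalent
path-length estimator `w * l / (V * N)` in (near-)non-absorbing voxels, so
the output is energy fluence per launched photon (mm^-2) and the
normalization is independent of the photon budget. Time of flight uses the
local refractive index, and scoring stops at a continuous-wave time gate.
Refractive-index mismatches (internal and at the external boundary against
n = 1) are handled with Snell/Fresnel at axis-aligned voxel faces; a purely
absorbing boundary is available. Russian roulette (threshold 1e-4, survival
probability 0.1) is unbiased and disabled in conservation tests, where
launched weight equals absorbed + escaped + gated weight to better than
1e-6 relative.

The random stream is counter-based: each photon's generator is seeded by
splitmix64 from (run seed, photon index) and advanced with xorshift64*, so
a run is reproducible bit-for-bit from its seed regardless of scheduling.

Validation: on a homogeneous medium the radially averaged fluence matches
the CW diffusion Green's function `exp(-mueff*r) / (4*pi*D*r)` (with
`D = 1/(3(mua+mus'))`, `mueff = sqrt(3*mua*(mua+mus'))`) within a few
percent in the diffusive regime, and the 10 dB-per-decade shot-noise law is
reproduced within the stated +-1.5 dB.

## Dynamic-range compression and dual-gain inference

Networks operate on `y = ln(c*x + 1)` (double precision throughout; at
c = 1e7 a single-precision round trip loses digits). Inference runs twice —
c = 1 and c = 1e7 — and merges voxel-wise on the *original* fluence with
threshold 0.03: brighter voxels take the low-gain output, the rest the
high-gain output. Volumes are never normalized by their maximum. Negative
log-space outputs (denoiser overshoot) clamp to zero before inversion.

## Denoiser architecture

Both stages learn in residual space (the body predicts a noise map that is
subtracted from its input):

* global stage — a DnCNN-style plain stack: conv(3^3) + ReLU, then
  conv + batch norm + ReLU blocks, then a conv head;
* local stage — a UNet-style encoder-decoder with average-pooling
  downsampling, transposed-convolution upsampling, batch normalization
  between the convolution / transposed-convolution / pooling layers, and
  skip concatenation;
* cascade — the local stage denoises the global stage's output; both are
  trained jointly end-to-end with a single loss on the final output.

Residual heads are zero-initialized, so an untrained network is the exact
identity and training starts from the no-op baseline. Padding inside
convolutions is zero "same" padding: its backprop adjoint is exact for the
hand-written gradients, and at desk scale border behavior is dominated by
the physics boundary conditions rather than the padding rule. Exact layer
depths/widths are configurable; the desk-scale defaults (global depth 5-8,
width 12-32; local 2-3 scales, base width 8-16) are declared choices, not
values inferred from any reference.

All layers, their backward passes, and the optimizer are implemented on
numpy arrays; gradients are verified against central finite differences in
the test suite.

Inference pads any input volume to the network stride multiple (edge
padding) and crops back, so output shape always equals input shape. For
bounded memory, `denoise_volume` tiles the volume into disjoint cores
processed with a halo of `overlap` voxels of true neighboring data; the
halo is discarded after inference. Wherever the halo covers the receptive
field this is exactly the whole-volume output, unlike feathered blending of
zero-padded patches, which leaves a receptive-field-wide error band at every
internal patch edge no matter the blend weights.

## Training

Loss: mini-batch mean of element-wise `|pred - clean|^n`, n = 2 by default.
Optimizer: Adam with decoupled weight decay 1e-4 applied to convolution
weights only (never biases or normalization parameters); linear warmup
(default 1000 mini-batch iterations) into cosine annealing to zero;
per-group gradient-norm clipping, 2 for normalization parameters and 1 for
everything else. Augmentation applies, each with probability 0.7, a
90-degree rotation about a random axis and a flip along a random axis,
identically to the noisy and clean volumes.

Pairs couple each lower photon level with the highest level of the same
phantom/source/gate, log-compressed at a gain drawn per pair uniformly from
{1, 1e7} (the two inference gains); the gain within a mini-batch is always
homogeneous, because batch-normalization statistics are meaningless across
the two-orders-of-magnitude scale difference of the two representations.
Validation MSE/SSIM/PSNR are recorded each epoch and the retained checkpoint
is the best by rank-sum over (MSE down, SSIM up, PSNR up), ties to the
earliest epoch.

Desk-scale training runs (tests, examples) override the schedule to
base_lr 1e-3 with ~30 warmup iterations: with tens of iterations per epoch,
a 1000-iteration warmup would consume the entire run at near-zero rate.

## Evaluation metrics

Global metrics are computed on log-compressed volumes (default gain 1e7,
recorded per report): MSE/MAE; 3D SSIM with Gaussian-weighted local moments
(sigma 5 voxels, kernel truncated at 3 sigma, reflective borders,
C1 = (0.01*L)^2, C2 = (0.03*L)^2 with L = 40); PSNR as
`20*log10(Imax/RMSE)` with Imax = 40, the ceiling of the compressed range —
so `psnr = 20*log10(Imax) - 10*log10(mse)` holds identically.

Local metrics come from stacks of independently seeded repetitions
(reference N = 100; desk-scale runs use 20-50): voxel SNR
`20*log10(mu/sigma)` with the population (1/N) standard deviation, defined
where both mean and deviation are positive; delta-SNR averaged over voxels
valid in both stacks (and over the "effective" region improved by more than
0.5 dB); photon multiplier `MF = 10^(dSNR/10)`. Cross-section profiles
(mean and SNR along an axis-aligned line) support the unbiasedness check:
denoising should not shift the mean fluence along the profile.

## Desk-scale study conditions

The reference experiment behind this package trains on 1500 domains of
64^3 voxels at photon levels 1e5-1e9 for 1500 epochs on a multi-GPU server.
This package reproduces the *method* at desk scale on one CPU:

* miniature catalog: 12 training + 2 validation random domains at 20^3,
  photon levels 1e3/1e4/1e5 (10-fold ladder; the highest level is the clean
  reference), time gates drawn from the low end (0.1-0.3 ns) of the U[0.1,1]
  ns study range to bound per-photon path lengths;
* toy cascade: global depth 6 width 12, local 2 scales base width 12;
  50 epochs with training gains drawn log-uniformly from the decade ladder
  {1, ..., 1e7} so the network sees the full amplitude continuum between
  the two inference gains.

What passing desk-scale tests shows: the full pipeline — generation,
transport, compression, training, dual-gain inference, evaluation — learns a
denoiser that strictly improves mean voxel SNR on held-out data and leaves
the cross-section mean fluence essentially unchanged. What it does not show:
the headline 14-19 dB improvements of the full-scale study, which require
orders of magnitude more data, capacity and training; desk-scale SNR gains
are fractions of a dB to a few dB. Synthetic phantoms also do not capture
anatomical structure, wavelength dependence, or curved internal boundaries
(voxelized faces only).

## Known limitations

* The voxel MC uses axis-aligned Fresnel faces; curved-interface accuracy is
  limited by voxelization.
* Very high `mus` draws (g close to 1) make individual domains expensive;
  the time gate bounds the cost.
* The 2-scale/3-scale toy UNet has a limited receptive field: distinguishing
  the c = 1 representation from the deep-noise floor of the c = 1e7
  representation relies on near-global context, and small models can bias
  bright voxels in the low-gain pass.
* PSNR of identical volumes is reported as +inf (sentinel), and delta-SNR's
  effective region may be empty (NaN) when no voxel improves beyond 0.5 dB.
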