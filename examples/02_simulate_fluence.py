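"""Run the voxel Monte Carlo forward solver on a scaled homogeneous benchmark.

Simulates a 30 mm cube with an isotropic source at its center and prints the
weight conservation audit plus the shot-noise behavior of the fluence map:
ten times more photons should buy roughly 10 dB of voxel SNR.
"""

import dataclasses

import numpy as np

from mcdn import benchmark_domain, run_repetitions, simulate_fluence, snr_map

phantom, source, spec = benchmark_domain("b1", scale_factor=0.3,
                                         photon_count=2000, seed=1)
spec = dataclasses.replace(spec, roulette_enabled=False)
vol, stats = simulate_fluence(phantom, source, spec)
print(f"launched weight   : {stats.total_launched_weight:.0f}")
print(f"absorbed weight   : {stats.total_absorbed_weight:.1f}")
print(f"escaped weight    : {stats.total_escaped_weight:.1f}")
print(f"gated-out weight  : {stats.total_time_gated_out_weight:.1f}")
print(f"conservation error: {stats.conservation_error():.2e}")
print(f"fluence: max {vol.values.max():.3f} mm^-2/photon, "
      f"{np.count_nonzero(vol.values)} of {vol.values.size} voxels reached")

for photons in (1000, 10000):
    stack = run_repetitions(phantom, source,
                            dataclasses.replace(spec, photon_count=photons),
                            n_reps=20, base_seed=100)
    m = snr_map(stack, photon_count=photons)
    print(f"{photons:6d} photons: mean voxel SNR "
          f"{np.nanmean(m.values[m.valid]):6.2f} dB over {m.valid.sum()} voxels")
print("The ~10 dB gap per photon decade is the shot-noise signature that the "
      "denoiser is meant to buy back without extra photons.")
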