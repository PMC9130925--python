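"""Voxelated photon-packet Monte Carlo forward solver.

Photon packets random-walk through the labeled voxel grid: step lengths are
sampled from the local scattering coefficient, deflection angles from the
Henyey-Greenstein phase function, and absorption is handled by continuous
weight attenuation ``w *= exp(-mua * l)`` along each segment. Fluence is
scored with the absorbed-energy estimator ``deposited / (mua * V * N)``; in
(near) non-absorbing voxels the equivalent path-length estimator
``w * l / (V * N)`` is used, so the output is energy fluence per launched
photon (mm^-2). Time of flight accumulates as ``l * n / c0`` and deposition
stops at the continuous-wave time gate.

Internal and external refractive-index mismatches are handled with
Snell/Fresnel at axis-aligned voxel faces; the external boundary is either
absorbing or Fresnel-matched against n = 1. The random stream is counter
based: each photon's generator is seeded from (run seed, photon index) via
splitmix64 and advanced with xorshift64*, so results are independent of
execution order and fully determined by the run seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit

from .phantoms import Phantom, SourceSpec

__all__ = [
    "SimulationSpec",
    "FluenceVolume",
    "RunStats",
    "hg_sample",
    "simulate_fluence",
    "run_repetitions",
    "benchmark_domain",
    "DEFAULT_BENCHMARK_PROPERTIES",
]

C0_MM_PER_NS = 299.792458  # vacuum speed of light

BOUNDARY_ABSORBING = 0
BOUNDARY_FRESNEL = 1


@dataclasses.dataclass
class SimulationSpec:
    """One forward run: photon budget, seed, gate, grid and termination policy."""

    photon_count: int
    seed: int
    time_gate: float  # ns
    voxel_size: float = 1.0  # mm
    boundary: str = "fresnel"  # "absorbing" | "fresnel"
    roulette_threshold: float = 1e-4
    roulette_survival_prob: float = 0.1
    roulette_enabled: bool = True

    def __post_init__(self):
        if self.photon_count < 1:
            raise ValueError("photon_count must be >= 1")
        if self.time_gate <= 0:
            raise ValueError("time_gate must be positive")
        if not (0 < self.roulette_survival_prob <= 1):
            raise ValueError("roulette_survival_prob must be in (0, 1]")
        if self.boundary not in ("absorbing", "fresnel"):
            raise ValueError("boundary must be 'absorbing' or 'fresnel'")


@dataclasses.dataclass
class FluenceVolume:
    """CW fluence map from one seeded run, per launched photon (mm^-2)."""

    values: np.ndarray
    voxel_size: float
    photon_count: int
    seed: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fluence must be finite everywhere")
        if self.values.min() < 0:
            raise ValueError("fluence must be non-negative")

    @property
    def grid_shape(self):
        return self.values.shape


@dataclasses.dataclass
class RunStats:
    """Weight conservation audit for one run (per-photon normalized totals)."""

    total_launched_weight: float
    total_absorbed_weight: float
    total_escaped_weight: float
    total_time_gated_out_weight: float
    total_rouletted_weight: float = 0.0

    def conservation_error(self) -> float:
        lost = (self.total_absorbed_weight + self.total_escaped_weight
                + self.total_time_gated_out_weight + self.total_rouletted_weight)
        return abs(self.total_launched_weight - lost) / self.total_launched_weight


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True, inline="always")
def _splitmix64(x):
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = x
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, fastmath=True, inline="always")
def _rand(state):
    # xorshift64*; returns (u in [0,1), new_state)
    s = state
    s ^= s >> np.uint64(12)
    s ^= (s << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s ^= s >> np.uint64(27)
    out = (s * np.uint64(0x2545F4914F6CDD1D)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return (out >> np.uint64(11)) * (1.0 / 9007199254740992.0), s


@njit(cache=True, fastmath=True, inline="always")
def _hg_cost(g, u):
    if abs(g) < 1e-6:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if cost > 1.0:
        cost = 1.0
    elif cost < -1.0:
        cost = -1.0
    return cost


@njit(cache=True, fastmath=True, inline="always")
def _scatter(ux, uy, uz, cost, phi):
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = np.cos(phi)
    sinp = np.sin(phi)
    if abs(uz) > 0.99999:
        nux = sint * cosp
        nuy = sint * sinp
        nuz = cost * (1.0 if uz >= 0 else -1.0)
    else:
        den = np.sqrt(1.0 - uz * uz)
        nux = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
        nuy = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
        nuz = -sint * cosp * den + uz * cost
    norm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    return nux / norm, nuy / norm, nuz / norm


@njit(cache=True, fastmath=True)
def _transport_kernel(labels, mua_t, mus_t, g_t, n_t,
                      src_x, src_y, src_z, src_dx, src_dy, src_dz, isotropic,
                      n_photons, seed, time_gate, vs, boundary_mode,
                      roulette_on, w_thresh, p_surv, acc, stats):
    nx, ny, nz = labels.shape
    inv_c0 = 1.0 / C0_MM_PER_NS
    for ip in range(n_photons):
        state = _splitmix64(np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15)
                            + np.uint64(ip))
        state = _splitmix64(state)
        if state == np.uint64(0):
            state = np.uint64(0xDEADBEEF)
        # launch
        x = src_x
        y = src_y
        z = src_z
        if isotropic:
            u, state = _rand(state)
            cost = 2.0 * u - 1.0
            u, state = _rand(state)
            phi = 2.0 * np.pi * u
            sint = np.sqrt(max(0.0, 1.0 - cost * cost))
            dx = sint * np.cos(phi)
            dy = sint * np.sin(phi)
            dz = cost
        else:
            dx = src_dx
            dy = src_dy
            dz = src_dz
        w = 1.0
        t = 0.0
        ix = int(x / vs)
        iy = int(y / vs)
        iz = int(z / vs)
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            stats[2] += w  # launched outside: counts as escaped
            stats[0] += 1.0
            continue
        u, state = _rand(state)
        scat_left = -np.log(1.0 - u)  # remaining scattering optical depth
        alive = True
        while alive:
            lbl = labels[ix, iy, iz]
            mua = mua_t[lbl]
            mus = mus_t[lbl]
            gg = g_t[lbl]
            nn = n_t[lbl]
            # distance to voxel boundary along direction; remember exit axis
            d_b = 1e30
            axis = -1
            step_sign = 0
            if dx > 1e-12:
                dd = ((ix + 1) * vs - x) / dx
                if dd < d_b:
                    d_b = dd
                    axis = 0
                    step_sign = 1
            elif dx < -1e-12:
                dd = (ix * vs - x) / dx
                if dd < d_b:
                    d_b = dd
                    axis = 0
                    step_sign = -1
            if dy > 1e-12:
                dd = ((iy + 1) * vs - y) / dy
                if dd < d_b:
                    d_b = dd
                    axis = 1
                    step_sign = 1
            elif dy < -1e-12:
                dd = (iy * vs - y) / dy
                if dd < d_b:
                    d_b = dd
                    axis = 1
                    step_sign = -1
            if dz > 1e-12:
                dd = ((iz + 1) * vs - z) / dz
                if dd < d_b:
                    d_b = dd
                    axis = 2
                    step_sign = 1
            elif dz < -1e-12:
                dd = (iz * vs - z) / dz
                if dd < d_b:
                    d_b = dd
                    axis = 2
                    step_sign = -1
            if d_b < 0.0:
                d_b = 0.0
            d_s = scat_left / mus if mus > 0.0 else 1e30
            d_t = (time_gate - t) * C0_MM_PER_NS / nn
            event = 0  # 0 boundary, 1 scatter, 2 gate
            d = d_b
            if d_s < d:
                d = d_s
                event = 1
            if d_t < d:
                d = d_t
                event = 2
            # deposit along segment of length d in current voxel
            if mua > 1e-12:
                wfac = np.exp(-mua * d)
                dep = w * (1.0 - wfac)
                acc[ix, iy, iz] += dep / mua
                stats[1] += dep
                w *= wfac
            else:
                acc[ix, iy, iz] += w * d
            x += d * dx
            y += d * dy
            z += d * dz
            t += d * nn * inv_c0
            if event == 2:
                stats[3] += w
                alive = False
            elif event == 1:
                u, state = _rand(state)
                scat_left = -np.log(1.0 - u)
                u, state = _rand(state)
                cost = _hg_cost(gg, u)
                u, state = _rand(state)
                dx, dy, dz = _scatter(dx, dy, dz, cost, 2.0 * np.pi * u)
            else:
                scat_left -= d * mus
                if scat_left < 0.0:
                    scat_left = 0.0
                jx = ix
                jy = iy
                jz = iz
                if axis == 0:
                    jx += step_sign
                elif axis == 1:
                    jy += step_sign
                else:
                    jz += step_sign
                outside = jx < 0 or jx >= nx or jy < 0 or jy >= ny or jz < 0 or jz >= nz
                if outside and boundary_mode == BOUNDARY_ABSORBING:
                    stats[2] += w
                    alive = False
                else:
                    n2 = 1.0 if outside else n_t[labels[jx, jy, jz]]
                    if n2 != nn:
                        # Fresnel at the axis-aligned face
                        if axis == 0:
                            ci = abs(dx)
                        elif axis == 1:
                            ci = abs(dy)
                        else:
                            ci = abs(dz)
                        if ci > 1.0:
                            ci = 1.0
                        si2 = 1.0 - ci * ci
                        st2 = (nn / n2) * (nn / n2) * si2
                        reflect = False
                        if st2 >= 1.0:
                            reflect = True  # total internal reflection
                        else:
                            ct = np.sqrt(1.0 - st2)
                            rs = (nn * ci - n2 * ct) / (nn * ci + n2 * ct)
                            rp = (nn * ct - n2 * ci) / (nn * ct + n2 * ci)
                            R = 0.5 * (rs * rs + rp * rp)
                            u, state = _rand(state)
                            if u < R:
                                reflect = True
                        if reflect:
                            if axis == 0:
                                dx = -dx
                            elif axis == 1:
                                dy = -dy
                            else:
                                dz = -dz
                            # stay in the current voxel
                        else:
                            # refract: scale tangential components
                            ratio = nn / n2
                            if axis == 0:
                                sgn = 1.0 if dx >= 0 else -1.0
                                dy *= ratio
                                dz *= ratio
                                dx = sgn * ct
                            elif axis == 1:
                                sgn = 1.0 if dy >= 0 else -1.0
                                dx *= ratio
                                dz *= ratio
                                dy = sgn * ct
                            else:
                                sgn = 1.0 if dz >= 0 else -1.0
                                dx *= ratio
                                dy *= ratio
                                dz = sgn * ct
                            nrm = np.sqrt(dx * dx + dy * dy + dz * dz)
                            dx /= nrm
                            dy /= nrm
                            dz /= nrm
                            if outside:
                                stats[2] += w
                                alive = False
                            else:
                                ix = jx
                                iy = jy
                                iz = jz
                    else:
                        if outside:
                            stats[2] += w
                            alive = False
                        else:
                            ix = jx
                            iy = jy
                            iz = jz
            # Russian roulette
            if alive and roulette_on and w < w_thresh:
                u, state = _rand(state)
                if u < p_surv:
                    w /= p_surv
                else:
                    stats[4] += w
                    alive = False
        stats[0] += 1.0
    return


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def hg_sample(g: float, u) -> np.ndarray | float:
    """Sample cos(theta) from the Henyey-Greenstein phase function.

    Inverse-CDF: for g = 0 this reduces to the isotropic ``2u - 1``; the mean
    of the returned cosine equals g.
    """
    if not (-1.0 < g < 1.0):
        raise ValueError("anisotropy g must lie in (-1, 1)")
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr < 0) | (u_arr >= 1)):
        raise ValueError("uniform deviate u must lie in [0, 1)")
    if abs(g) < 1e-12:
        out = 2.0 * u_arr - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u_arr)
        out = np.clip((1.0 + g * g - tmp * tmp) / (2.0 * g), -1.0, 1.0)
    return out if np.ndim(u) else float(out)


def _property_tables(phantom: Phantom):
    labels = phantom.label_grid
    unique = np.unique(labels)
    lut = np.zeros(int(unique.max()) + 1, dtype=np.int32)
    for i, lbl in enumerate(unique):
        lut[lbl] = i
    dense = lut[labels]
    mua = np.empty(len(unique))
    mus = np.empty(len(unique))
    g = np.empty(len(unique))
    n = np.empty(len(unique))
    for i, lbl in enumerate(unique):
        p = phantom.properties[int(lbl)]
        mua[i], mus[i], g[i], n[i] = p.mua, p.mus, p.g, p.n
    return np.ascontiguousarray(dense.astype(np.int32)), mua, mus, g, n


def simulate_fluence(phantom: Phantom, source: SourceSpec, spec: SimulationSpec
                     ) -> tuple[FluenceVolume, RunStats]:
    """Run one seeded Monte Carlo forward simulation.

    Returns the per-photon-normalized CW fluence volume and a weight
    conservation audit. Deterministic under ``spec.seed``.
    """
    pos = np.asarray(source.position, dtype=float)
    extent = phantom.extent_mm
    if np.any(pos <= 0) or np.any(pos >= extent):
        raise ValueError(f"source position {tuple(pos)} not strictly inside "
                         f"domain extent {tuple(extent)} mm")
    labels, mua, mus, g, n = _property_tables(phantom)
    acc = np.zeros(labels.shape, dtype=np.float64)
    stats = np.zeros(5, dtype=np.float64)
    direction = np.asarray(source.direction, dtype=float)
    _transport_kernel(
        labels, mua, mus, g, n,
        pos[0], pos[1], pos[2], direction[0], direction[1], direction[2],
        source.kind == "isotropic",
        int(spec.photon_count), int(spec.seed) & 0x7FFFFFFFFFFFFFFF,
        float(spec.time_gate), float(spec.voxel_size),
        BOUNDARY_ABSORBING if spec.boundary == "absorbing" else BOUNDARY_FRESNEL,
        bool(spec.roulette_enabled), float(spec.roulette_threshold),
        float(spec.roulette_survival_prob), acc, stats)
    voxel_volume = spec.voxel_size ** 3
    fluence = acc / (voxel_volume * spec.photon_count)
    vol = FluenceVolume(values=fluence, voxel_size=spec.voxel_size,
                        photon_count=spec.photon_count, seed=spec.seed)
    run_stats = RunStats(
        total_launched_weight=stats[0],
        total_absorbed_weight=stats[1],
        total_escaped_weight=stats[2],
        total_time_gated_out_weight=stats[3],
        total_rouletted_weight=stats[4],
    )
    return vol, run_stats


def run_repetitions(phantom: Phantom, source: SourceSpec, spec: SimulationSpec,
                    n_reps: int, base_seed: int | None = None
                    ) -> list[FluenceVolume]:
    """Run ``n_reps`` independently seeded repetitions (seeds base, base+1, ...)."""
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    base_seed = spec.seed if base_seed is None else base_seed
    out = []
    for r in range(n_reps):
        rep_spec = dataclasses.replace(spec, seed=base_seed + r)
        try:
            vol, _ = simulate_fluence(phantom, source, rep_spec)
        except Exception as err:
            raise RuntimeError(f"repetition {r} (seed {base_seed + r}) failed") from err
        out.append(vol)
    return out


DEFAULT_BENCHMARK_PROPERTIES = {
    # Benchmark optical properties live here (overridable), not in the physics.
    "background": {"mua": 0.005, "musp": 1.0, "g": 0.9, "n": 1.37},
    "absorber": {"mua": 0.05, "musp": 1.0, "g": 0.9, "n": 1.37},
    "refractive": {"mua": 0.005, "musp": 1.0, "g": 0.9, "n": 1.0},
}


def _props_from_config(cfg: dict) -> "OpticalProperties":
    from .phantoms import OpticalProperties

    g = cfg["g"]
    mus = cfg["musp"] / (1.0 - g)
    return OpticalProperties(mua=cfg["mua"], mus=mus, g=g, n=cfg["n"])


def benchmark_domain(name: str, scale_factor: float = 1.0,
                     photon_count: int = 10_000, seed: int = 0,
                     time_gate: float = 1.0,
                     properties: dict | None = None
                     ) -> tuple[Phantom, SourceSpec, SimulationSpec]:
    """Return a scaled standard benchmark geometry.

    ``b1``: homogeneous cube (100 mm side at scale 1, 1-mm voxels);
    ``b2``: the same cube with a centered cubic absorber (40 mm side at scale 1);
    ``b3``: the same cube with a centered refractive inclusion.
    The isotropic source sits at the cube center.
    """
    from .phantoms import Phantom as _Phantom

    valid = ("b1", "b2", "b3")
    if name not in valid:
        raise ValueError(f"unknown benchmark {name!r}; valid names: {valid}")
    if not (0 < scale_factor <= 1):
        raise ValueError("scale_factor must be in (0, 1]")
    props = dict(DEFAULT_BENCHMARK_PROPERTIES)
    if properties:
        props.update(properties)
    side = max(4, int(round(100 * scale_factor)))
    grid = np.zeros((side, side, side), dtype=np.int32)
    table = {0: _props_from_config(props["background"])}
    if name in ("b2", "b3"):
        inc = max(1, int(round(40 * scale_factor)))
        lo = (side - inc) // 2
        hi = lo + inc
        grid[lo:hi, lo:hi, lo:hi] = 1
        key = "absorber" if name == "b2" else "refractive"
        table[1] = _props_from_config(props[key])
    phantom = _Phantom(label_grid=grid, properties=table, voxel_size=1.0)
    center = tuple(side / 2.0 for _ in range(3))
    source = SourceSpec(kind="isotropic", position=center)
    spec = SimulationSpec(photon_count=photon_count, seed=seed,
                          time_gate=time_gate, voxel_size=1.0)
    return phantom, source, spec
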