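"""End-to-end orchestration: generate -> simulate -> train -> denoise -> evaluate.

A pipeline run is driven by one JSON-serializable config whose global seed
deterministically derives every stage seed. Each stage writes its artifacts
under the run directory together with a provenance sidecar (config hash,
stage seed) and a completion marker, so a rerun resumes after completed
stages. ``make_fixtures`` builds the miniature in-memory catalog (a handful
of small phantoms with a short ladder of photon levels) used by the tests and
examples as a desk-scale stand-in for a full training corpus.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from .io import load_volume, save_json, save_volume
from .phantoms import Phantom, SourceSpec, load_phantom, random_phantom, \
    sample_simulation_config, generate_dataset
from .transport import FluenceVolume, SimulationSpec, simulate_fluence

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "FixtureSet", "run_pipeline", "make_fixtures"]


@dataclasses.dataclass
class PipelineConfig:
    """Configuration for a full pipeline run; round-trips through JSON."""

    seed: int = 0
    stages: tuple[str, ...] = ("generate", "simulate", "train", "denoise",
                               "evaluate")
    n_domains: int = 4
    n_val_domains: int = 2
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 1.0
    photon_levels: tuple[int, ...] = (1000, 10000, 100000)
    clean_level: int = 100000
    epochs: int = 5
    batch_size: int = 2
    global_depth: int = 4
    global_width: int = 8
    local_scales: int = 2
    local_width: int = 8
    merge_threshold: float = 0.03
    low_gain: float = 1.0
    high_gain: float = 1e7
    n_range: tuple[float, float] = (1.0, 10.0)

    _KNOWN_STAGES = ("generate", "simulate", "train", "denoise", "evaluate")

    def __post_init__(self):
        for s in self.stages:
            if s not in self._KNOWN_STAGES:
                raise ValueError(f"unknown stage {s!r}")
        if self.clean_level not in self.photon_levels:
            raise ValueError("clean_level must be one of photon_levels")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["grid_shape"] = list(self.grid_shape)
        d["photon_levels"] = list(self.photon_levels)
        d["n_range"] = list(self.n_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("stages", "grid_shape", "photon_levels", "n_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        idx = self._KNOWN_STAGES.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(self._KNOWN_STAGES))[idx]
        return int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


@dataclasses.dataclass
class FixtureSet:
    """Miniature catalog of phantoms + fluence ladders for tests and demos."""

    domains: dict  # name -> {"phantom", "source", "time_gate", "fluence": {level: FluenceVolume}}
    train_names: list[str]
    val_names: list[str]
    photon_levels: tuple[int, ...]
    clean_level: int
    seed: int

    def fluence_by_domain(self, names=None) -> dict[str, dict[int, np.ndarray]]:
        names = names if names is not None else sorted(self.domains)
        return {
            name: {lvl: vol.values for lvl, vol in self.domains[name]["fluence"].items()}
            for name in names
        }

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.domains):
            dom = self.domains[name]
            h.update(dom["phantom"].content_hash().encode())
            for lvl in sorted(dom["fluence"]):
                h.update(np.ascontiguousarray(dom["fluence"][lvl].values))
        return h.hexdigest()


def make_fixtures(seed: int = 1234, out=None, n_train: int = 12, n_val: int = 2,
                  grid_shape=(20, 20, 20),
                  photon_levels: tuple[int, ...] = (1000, 10000, 100000),
                  n_range: tuple[float, float] = (1.0, 10.0),
                  time_gate_range: tuple[float, float] = (0.1, 0.3)
                  ) -> FixtureSet:
    """Generate the miniature phantom + fluence catalog, bit-stable under seed.

    Photon levels ascend by a factor of 10; the highest level plays the role
    of the clean reference.
    """
    clean_level = max(photon_levels)
    root = np.random.SeedSequence(seed)
    domains = {}
    names = [f"train_{i}" for i in range(n_train)] + [f"val_{i}" for i in range(n_val)]
    for name, child in zip(names, root.spawn(len(names))):
        rng = np.random.default_rng(child)
        phantom = random_phantom(rng, grid_shape, 1.0, n_range=n_range)
        source, gate = sample_simulation_config(rng, phantom)
        gate = time_gate_range[0] + (gate - 0.1) / 0.9 \
            * (time_gate_range[1] - time_gate_range[0])
        run_seed = int(child.generate_state(2, dtype=np.uint32)[1] & 0x7FFFFFFF)
        fluence = {}
        for j, level in enumerate(photon_levels):
            spec = SimulationSpec(photon_count=level, seed=run_seed + j,
                                  time_gate=gate, voxel_size=1.0)
            vol, _ = simulate_fluence(phantom, source, spec)
            fluence[level] = vol
        domains[name] = {"phantom": phantom, "source": source,
                         "time_gate": gate, "fluence": fluence}
    fixtures = FixtureSet(
        domains=domains,
        train_names=[n for n in names if n.startswith("train_")],
        val_names=[n for n in names if n.startswith("val_")],
        photon_levels=tuple(photon_levels),
        clean_level=clean_level,
        seed=seed,
    )
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        manifest = []
        for name in names:
            dom = domains[name]
            save_volume(dom["phantom"].label_grid.astype(np.int16), 1.0,
                        out / f"{name}_labels.nii")
            save_json({str(k): v.to_dict() for k, v in dom["phantom"].properties.items()},
                      out / f"{name}_props.json")
            for lvl, vol in dom["fluence"].items():
                save_volume(vol.values.astype(np.float32), 1.0,
                            out / f"{name}_fluence_{lvl}.nii")
            manifest.append({
                "name": name, "source": dom["source"].to_dict(),
                "time_gate_ns": dom["time_gate"],
                "photon_levels": list(photon_levels),
            })
        save_json({"seed": seed, "hash": fixtures.content_hash(),
                   "domains": manifest}, out / "fixtures.json")
    return fixtures


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def _stage_done(run_dir: Path, stage: str) -> bool:
    return (run_dir / stage / ".done").exists()


def _mark_done(run_dir: Path, stage: str, config: PipelineConfig):
    save_json({"stage": stage, "config_hash": config.config_hash(),
               "stage_seed": config.stage_seed(stage)},
              run_dir / stage / ".done")


def run_pipeline(config: PipelineConfig, run_dir) -> Path:
    """Execute the requested stages in order under ``run_dir``; resumable."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    save_json(config.to_dict(), run_dir / "config.json")
    order = [s for s in config._KNOWN_STAGES if s in config.stages]
    for stage in order:
        if _stage_done(run_dir, stage):
            logger.info("stage %s already complete; skipping", stage)
            continue
        try:
            _STAGE_FNS[stage](config, run_dir)
        except Exception as err:
            raise RuntimeError(
                f"pipeline stage {stage!r} failed (artifacts under "
                f"{run_dir / stage})") from err
        _mark_done(run_dir, stage, config)
    return run_dir


def _stage_generate(config: PipelineConfig, run_dir: Path):
    out = run_dir / "generate"
    generate_dataset(config.n_domains + config.n_val_domains, config.grid_shape,
                     out, seed=config.stage_seed("generate"),
                     voxel_size=config.voxel_size, n_range=config.n_range)


def _stage_simulate(config: PipelineConfig, run_dir: Path):
    from .io import load_json

    gen = run_dir / "generate"
    out = run_dir / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    records = load_json(gen / "manifest.json")
    for i, rec in enumerate(records):
        phantom = load_phantom(gen, rec)
        source = SourceSpec.from_dict(rec["source"])
        for j, level in enumerate(config.photon_levels):
            spec = SimulationSpec(photon_count=level, seed=rec["seed"] + j,
                                  time_gate=rec["time_gate_ns"],
                                  voxel_size=config.voxel_size)
            vol, stats = simulate_fluence(phantom, source, spec)
            save_volume(vol.values.astype(np.float32), config.voxel_size,
                        out / f"domain_{i:04d}_fluence_{level}.nii")
            save_json(dataclasses.asdict(stats),
                      out / f"domain_{i:04d}_stats_{level}.json")


def _load_fluence_table(config: PipelineConfig, run_dir: Path):
    sim = run_dir / "simulate"
    n_total = config.n_domains + config.n_val_domains
    table = {}
    for i in range(n_total):
        table[f"domain_{i:04d}"] = {
            level: load_volume(sim / f"domain_{i:04d}_fluence_{level}.nii")[0]
            .astype(np.float64)
            for level in config.photon_levels
        }
    return table


def _stage_train(config: PipelineConfig, run_dir: Path):
    from .models import GlobalStageSpec, LocalStageSpec, build_cascade, \
        save_checkpoint
    from .training import TrainConfig, assemble_dataset, train

    table = _load_fluence_table(config, run_dir)
    names = sorted(table)
    train_names = names[: config.n_domains]
    val_names = names[config.n_domains:]
    seed = config.stage_seed("train")
    rng = np.random.default_rng(seed)
    levels = [lv for lv in config.photon_levels if lv < config.clean_level]
    train_pairs = assemble_dataset({n: table[n] for n in train_names}, levels,
                                   config.clean_level, rng=rng)
    val_pairs = assemble_dataset({n: table[n] for n in val_names}, levels,
                                 config.clean_level, rng=rng)
    model = build_cascade(
        GlobalStageSpec(depth=config.global_depth, width=config.global_width),
        LocalStageSpec(n_scales=config.local_scales, base_width=config.local_width),
        seed=seed)
    tconf = TrainConfig(epochs=config.epochs, batch_size=config.batch_size,
                        seed=seed)
    model, history = train(model, train_pairs, val_pairs, tconf)
    out = run_dir / "train"
    out.mkdir(parents=True, exist_ok=True)
    save_checkpoint(model, out / "model.npz")
    save_json(history.to_dict(), out / "history.json")


def _stage_denoise(config: PipelineConfig, run_dir: Path):
    from .models import load_checkpoint
    from .transforms import MergePolicy, dual_gain_denoise

    table = _load_fluence_table(config, run_dir)
    model = load_checkpoint(run_dir / "train" / "model.npz")
    policy = MergePolicy(threshold=config.merge_threshold,
                         low_gain=config.low_gain, high_gain=config.high_gain)
    out = run_dir / "denoise"
    out.mkdir(parents=True, exist_ok=True)
    noisy_level = min(config.photon_levels)
    for name in sorted(table):
        den = dual_gain_denoise(table[name][noisy_level], model, policy)
        save_volume(den.astype(np.float32), config.voxel_size,
                    out / f"{name}_denoised_{noisy_level}.nii")


def _stage_evaluate(config: PipelineConfig, run_dir: Path):
    from .metrics import mse, psnr, ssim3d
    from .transforms import forward_log

    table = _load_fluence_table(config, run_dir)
    out = run_dir / "evaluate"
    out.mkdir(parents=True, exist_ok=True)
    noisy_level = min(config.photon_levels)
    rows = {}
    for name in sorted(table):
        den, _ = load_volume(run_dir / "denoise" / f"{name}_denoised_{noisy_level}.nii")
        clean_log = forward_log(table[name][config.clean_level], config.high_gain)
        den_log = forward_log(np.maximum(np.asarray(den, dtype=np.float64), 0.0),
                              config.high_gain)
        noisy_log = forward_log(table[name][noisy_level], config.high_gain)
        rows[name] = {
            "mse_denoised": mse(den_log, clean_log),
            "mse_noisy": mse(noisy_log, clean_log),
            "ssim_denoised": ssim3d(den_log, clean_log),
            "psnr_denoised": psnr(den_log, clean_log),
        }
    save_json(rows, out / "report.json")


_STAGE_FNS = {
    "generate": _stage_generate,
    "simulate": _stage_simulate,
    "train": _stage_train,
    "denoise": _stage_denoise,
    "evaluate": _stage_evaluate,
}
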