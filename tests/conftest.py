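"""Shared fixtures: miniature generated datasets and a session-trained model.

Everything is generated programmatically at test time; nothing is read from
disk. The photon ladder (1e3/1e4/1e5) and toy cascade sizes are the package's
desk-scale study conditions.
"""

import dataclasses

import numpy as np
import pytest

import mcdn
from mcdn.phantoms import OpticalProperties, Phantom, SourceSpec

FIXTURE_SEED = 1234
PHOTON_LEVELS = (1000, 10000, 100000)
CLEAN_LEVEL = 100000
NOISY_LEVELS = [1000, 10000]

TOY_GLOBAL = mcdn.GlobalStageSpec(depth=6, width=12)
TOY_LOCAL = mcdn.LocalStageSpec(n_scales=2, base_width=12)
TOY_TRAIN = dict(epochs=50, batch_size=2, seed=0, base_lr=1e-3, warmup_iters=30)


def homogeneous_phantom(side=30, mua=0.01, musp=1.0, g=0.9, n=1.37,
                        voxel_size=1.0):
    """Uniform cube phantom with an isotropic source at its center."""
    props = {0: OpticalProperties(mua=mua, mus=musp / (1.0 - g), g=g, n=n)}
    phantom = Phantom(label_grid=np.zeros((side,) * 3, dtype=np.int32),
                      properties=props, voxel_size=voxel_size)
    source = SourceSpec(kind="isotropic",
                        position=(side * voxel_size / 2.0,) * 3)
    return phantom, source


@pytest.fixture(scope="session")
def fixture_set():
    return mcdn.make_fixtures(seed=FIXTURE_SEED, photon_levels=PHOTON_LEVELS)


@pytest.fixture(scope="session")
def training_pairs(fixture_set):
    rng = np.random.default_rng(0)
    train = mcdn.assemble_dataset(
        fixture_set.fluence_by_domain(fixture_set.train_names), NOISY_LEVELS,
        CLEAN_LEVEL, gain_policy="loguniform", rng=rng)
    val = mcdn.assemble_dataset(
        fixture_set.fluence_by_domain(fixture_set.val_names), NOISY_LEVELS,
        CLEAN_LEVEL, rng=rng)
    return train, val


@pytest.fixture(scope="session")
def trained_cascade(training_pairs):
    """Toy cascade trained once per session on the miniature catalog."""
    train, val = training_pairs
    model = mcdn.build_cascade(TOY_GLOBAL, TOY_LOCAL, seed=0)
    cfg = mcdn.TrainConfig(**TOY_TRAIN)
    model, history = mcdn.train(model, train, val, cfg)
    return model, history


@pytest.fixture()
def small_sim_spec():
    return mcdn.SimulationSpec(photon_count=500, seed=11, time_gate=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
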