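"""Training engine: loss, augmentation, dataset assembly, checkpoint choice."""

import dataclasses

import numpy as np
import pytest

import mcdn
from mcdn.metrics import mse
from mcdn.training import (
    History,
    TrainConfig,
    TrainingPair,
    assemble_dataset,
    augment_pair,
    ln_loss,
    select_best,
    train,
)


def _pair(rng, shape=(8, 8, 8), gain=1.0):
    return TrainingPair(noisy=rng.random(shape), clean=rng.random(shape),
                        gain=gain, noisy_photons=100, clean_photons=1000)


class TestLnLoss:
    def test_zero_on_identical(self, rng):
        x = rng.random((2, 1, 4, 4, 4))
        loss, grad = ln_loss(x, x.copy(), 2)
        assert loss == 0.0
        np.testing.assert_array_equal(grad, 0.0)

    def test_constant_difference_closed_form(self):
        x = np.zeros((2, 1, 3, 3, 3))
        assert ln_loss(x + 2.0, x, 2)[0] == pytest.approx(4.0)
        assert ln_loss(x + 2.0, x, 1)[0] == pytest.approx(2.0)

    def test_l1_dominates_l2_for_subunit_errors(self, rng):
        x = np.zeros((1, 1, 4, 4, 4))
        y = rng.uniform(0.01, 0.99, size=x.shape)
        assert ln_loss(y, x, 1)[0] >= ln_loss(y, x, 2)[0]

    def test_gradient_matches_finite_difference(self, rng):
        x = rng.random((1, 1, 3, 3, 3))
        t = rng.random(x.shape)
        for n in (1, 2):
            _, grad = ln_loss(x, t, n)
            eps = 1e-7
            idx = (0, 0, 1, 1, 1)
            xp = x.copy()
            xp[idx] += eps
            num = (ln_loss(xp, t, n)[0] - ln_loss(x, t, n)[0]) / eps
            assert grad[idx] == pytest.approx(num, rel=1e-4)

    def test_shape_and_exponent_validation(self, rng):
        x = rng.random((1, 1, 2, 2, 2))
        with pytest.raises(ValueError):
            ln_loss(x, x[:, :, :1], 2)
        with pytest.raises(ValueError):
            ln_loss(x, x, 3)


class TestAugmentation:
    def test_p_zero_is_identity(self, rng):
        pair = _pair(rng)
        out = augment_pair(pair, rng, p=0.0)
        np.testing.assert_array_equal(out.noisy, pair.noisy)
        np.testing.assert_array_equal(out.clean, pair.clean)

    def test_voxel_multiset_preserved(self, rng):
        pair = _pair(rng)
        out = augment_pair(pair, rng, p=1.0)
        np.testing.assert_array_equal(np.sort(out.noisy, axis=None),
                                      np.sort(pair.noisy, axis=None))

    def test_same_transform_applied_to_both(self, rng):
        # any error metric between noisy and clean is invariant under the
        # jointly applied rotation/flip
        pair = _pair(rng)
        ref = mse(pair.noisy, pair.clean)
        for _ in range(20):
            out = augment_pair(pair, rng, p=1.0)
            assert mse(out.noisy, out.clean) == pytest.approx(ref, rel=1e-12)

    def test_application_rate_matches_probability(self, rng, monkeypatch):
        import mcdn.training as tr

        calls = {"rot": 0}
        orig = np.rot90

        def counting_rot90(*args, **kwargs):
            calls["rot"] += 1
            return orig(*args, **kwargs)

        monkeypatch.setattr(tr.np, "rot90", counting_rot90)
        pair = _pair(rng)
        n = 5000
        for _ in range(n):
            augment_pair(pair, rng, p=0.7)
        rate = calls["rot"] / (2 * n)  # rot90 called once per volume of the pair
        assert 0.68 <= rate <= 0.72

    def test_non_cubic_rotation_rejected(self, rng):
        pair = TrainingPair(noisy=rng.random((6, 8, 10)),
                            clean=rng.random((6, 8, 10)), gain=1.0)
        with pytest.raises(ValueError, match="square"):
            for _ in range(50):  # rotation axis is random; any axis fails here
                augment_pair(pair, rng, p=1.0)


class TestAssembleDataset:
    def _table(self, rng, domains=3, shape=(6, 6, 6)):
        return {
            f"d{i}": {100: rng.random(shape), 1000: rng.random(shape),
                      10000: rng.random(shape)}
            for i in range(domains)
        }

    def test_pair_counting(self, rng):
        pairs = assemble_dataset(self._table(rng), [100, 1000], 10000, rng=rng)
        assert len(pairs) == 6
        assert all(p.clean_photons == 10000 for p in pairs)

    def test_missing_level_names_domain(self, rng):
        table = self._table(rng)
        del table["d1"][1000]
        with pytest.raises(ValueError, match="d1"):
            assemble_dataset(table, [100, 1000], 10000, rng=rng)

    def test_fixed_gain_policy(self, rng):
        pairs = assemble_dataset(self._table(rng), [100], 10000,
                                 gain_policy=1e7, rng=rng)
        assert {p.gain for p in pairs} == {1e7}

    def test_dual_gain_policy_uses_both_inference_gains(self, rng):
        pairs = assemble_dataset(self._table(rng, domains=20), [100, 1000],
                                 10000, gain_policy="dual", rng=rng)
        assert {p.gain for p in pairs} == {1.0, 1e7}

    def test_noisy_and_clean_volumes_differ(self, fixture_set):
        pairs = assemble_dataset(
            fixture_set.fluence_by_domain(fixture_set.train_names[:1]),
            [min(fixture_set.photon_levels)], fixture_set.clean_level,
            rng=np.random.default_rng(0))
        assert not np.array_equal(pairs[0].noisy, pairs[0].clean)


class TestSelectBest:
    def _history(self, mses, ssims, psnrs):
        return History(train_loss=[0.0] * len(mses), val_mse=list(mses),
                       val_ssim=list(ssims), val_psnr=list(psnrs))

    def test_single_epoch(self):
        h = self._history([1.0], [0.5], [10.0])
        assert select_best(h, "composite") == 0

    def test_strictly_improving_psnr_selects_last(self):
        h = self._history([3, 2, 1], [0.1, 0.2, 0.3], [10, 20, 30])
        assert select_best(h, "psnr") == 2

    def test_composite_rank_sum_with_conflicting_metrics(self):
        # epoch ranks (lower better): mse -> [0,1,2]; ssim -> [2,0,1];
        # psnr -> [1,2,0]; totals [3,3,3] -> tie broken to earliest epoch
        h = self._history([1.0, 2.0, 3.0], [0.7, 0.9, 0.8], [20, 10, 30])
        assert select_best(h, "composite") == 0

    def test_mse_argmin(self):
        h = self._history([3.0, 1.0, 2.0], [0] * 3, [0] * 3)
        assert select_best(h, "mse") == 1

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            select_best(self._history([1], [1], [1]), "accuracy")

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            select_best(History())


class TestTrainLoop:
    def _toy_setup(self, rng, n_pairs=4, shape=(8, 8, 8)):
        pairs = [
            TrainingPair(noisy=rng.random(shape) * 5,
                         clean=rng.random(shape) * 5, gain=1.0)
            for _ in range(n_pairs)
        ]
        model = mcdn.build_cascade(mcdn.GlobalStageSpec(depth=3, width=8),
                                   mcdn.LocalStageSpec(n_scales=2, base_width=8),
                                   seed=0)
        return model, pairs

    def test_seeded_runs_reproduce_history(self, rng):
        cfg = TrainConfig(epochs=2, batch_size=2, seed=5, base_lr=1e-3,
                          warmup_iters=5)
        h = []
        for _ in range(2):
            model, pairs = self._toy_setup(np.random.default_rng(1))
            _, hist = train(model, pairs, pairs[:2], cfg)
            h.append(hist)
        assert h[0].train_loss == h[1].train_loss
        assert h[0].val_mse == h[1].val_mse

    def test_smoke_training_reduces_loss(self):
        rng = np.random.default_rng(3)
        base = rng.random((8, 8, 8)) * 3
        pairs = [
            TrainingPair(noisy=base + rng.normal(0, 0.5, base.shape),
                         clean=base, gain=1.0)
            for _ in range(10)
        ]
        model, _ = self._toy_setup(rng, n_pairs=0)
        cfg = TrainConfig(epochs=5, batch_size=2, seed=0, base_lr=1e-3,
                          warmup_iters=5)
        _, hist = train(model, pairs, pairs[:3], cfg)
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert hist.best_epoch is not None

    def test_empty_dataset_rejected(self, rng):
        model, pairs = self._toy_setup(rng)
        with pytest.raises(ValueError):
            train(model, [], pairs, TrainConfig(epochs=1))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(loss_exponent=3)
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)

    def test_pair_invariants(self, rng):
        with pytest.raises(ValueError):
            TrainingPair(noisy=rng.random((4, 4, 4)),
                         clean=rng.random((4, 4, 5)), gain=1.0)
        with pytest.raises(ValueError):
            TrainingPair(noisy=rng.random((4, 4, 4)),
                         clean=rng.random((4, 4, 4)), gain=1.0,
                         noisy_photons=1000, clean_photons=100)
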