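"""Loss formulas, augmentation, mixup, accumulation and the two-stage trainer."""

import dataclasses

import numpy as np
import pytest

from neurodg import (AugmentFlags, ClassPrior, ModelConfig, augment, class_weights,
                     mixup_batch, sim_loss, total_loss, wce_loss)
from neurodg.autodiff import Adam
from neurodg.network import AttentionNet3D
from neurodg.train import (AttentionGuidedClassifier, TrainConfig, _one_hot,
                           accumulate_and_step, train_stage1, train_stage2)


class TestClassWeights:
    def test_balanced_counts_give_equal_weights(self):
        w = class_weights(np.repeat([0, 1, 2], 10))
        np.testing.assert_allclose(w, w[0])

    def test_inverse_count_ratios(self):
        w = class_weights(np.repeat([0, 1, 2], [30, 15, 5]))
        np.testing.assert_allclose(w / w[0], [1.0, 2.0, 6.0])

    def test_missing_class_error_names_the_class(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            class_weights(np.array([0, 0, 2, 2]), n_classes=3)


class TestWceLoss:
    def test_perfect_one_hot_predictions_give_zero(self):
        p = np.eye(3)[[0, 1, 2]]
        assert wce_loss(p, np.array([0, 1, 2]), np.ones(3)) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_predictions_equal_weights_is_ln3(self):
        p = np.full((4, 3), 1 / 3)
        assert wce_loss(p, np.array([0, 1, 2, 0]), np.ones(3)) == pytest.approx(np.log(3))

    def test_matches_per_sample_loop_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(3), size=8)
        y = rng.integers(0, 3, size=8)
        w = np.array([0.5, 1.0, 2.0])
        expected = np.mean([-w[yi] * np.log(pi[yi]) for pi, yi in zip(p, y)])
        assert wce_loss(p, y, w) == pytest.approx(expected, abs=1e-12)

    def test_zero_probability_at_true_class_is_clamped(self):
        p = np.array([[1.0, 0.0, 0.0]])
        v = wce_loss(p, np.array([1]), np.ones(3))
        assert np.isfinite(v) and v > 20  # -log(1e-12) ~ 27.6


class TestSimLoss:
    def _priors(self, grids):
        return [ClassPrior(k, g, 1) for k, g in enumerate(grids)]

    def test_zero_iff_attention_equals_priors(self):
        rng = np.random.default_rng(1)
        grids = [rng.random((2, 2, 2)) for _ in range(3)]
        att = np.stack(grids)[None]
        assert sim_loss(att, self._priors(grids)) == 0.0
        att2 = att.copy()
        att2[0, 1, 0, 0, 0] += 0.5
        assert sim_loss(att2, self._priors(grids)) > 0.0

    def test_single_voxel_unit_distance(self):
        att = np.array([1.0, 0.0, 0.0]).reshape(1, 3, 1, 1, 1)
        priors = self._priors([np.zeros((1, 1, 1))] * 3)
        assert sim_loss(att, priors) == pytest.approx(1.0)

    def test_matches_voxel_loop_oracle(self):
        rng = np.random.default_rng(2)
        att = rng.random((3, 3, 2, 2, 2))
        grids = [rng.random((2, 2, 2)) for _ in range(3)]
        expected = np.mean([
            sum(np.sqrt(((att[i, k] - grids[k]) ** 2).sum()) for k in range(3))
            for i in range(3)
        ])
        assert sim_loss(att, self._priors(grids)) == pytest.approx(expected, abs=1e-12)

    def test_absent_prior_is_an_error(self):
        att = np.zeros((1, 3, 2, 2, 2))
        priors = [ClassPrior(0, np.zeros((2, 2, 2)), 1), ClassPrior(1, None, 0),
                  ClassPrior(2, np.zeros((2, 2, 2)), 1)]
        with pytest.raises(ValueError, match="absent"):
            sim_loss(att, priors)

    def test_true_class_only_scope(self):
        rng = np.random.default_rng(3)
        att = rng.random((2, 3, 2, 2, 2))
        grids = [rng.random((2, 2, 2)) for _ in range(3)]
        y = np.array([1, 2])
        expected = np.mean([
            np.sqrt(((att[i, y[i]] - grids[y[i]]) ** 2).sum()) for i in range(2)
        ])
        got = sim_loss(att, self._priors(grids), sim_scope="true_class_only", labels=y)
        assert got == pytest.approx(expected, abs=1e-12)


def test_total_loss_arithmetic():
    assert total_loss(1.0, 2.0, 0.5) == 2.0
    assert total_loss(0.7, 123.0, 0.0) == 0.7
    assert TrainConfig().lam == 5e-5  # reference default for full-scale volumes


class TestAugment:
    def test_all_flags_off_is_identity_on_unit_range(self):
        v = np.random.default_rng(0).random((8, 8, 8))
        out = augment(v, AugmentFlags(), seed=3)
        np.testing.assert_array_equal(out, v)

    @pytest.mark.parametrize("flags", [
        AugmentFlags(contrast=True),
        AugmentFlags(bias_field=True),
        AugmentFlags(crop_upsample=True),
        AugmentFlags(True, True, True),
    ])
    def test_output_in_unit_range_and_same_shape(self, flags):
        v = np.random.default_rng(1).random((8, 10, 12))
        out = augment(v, flags, seed=5)
        assert out.shape == v.shape
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_deterministic_per_seed(self):
        v = np.random.default_rng(2).random((8, 8, 8))
        flags = AugmentFlags(True, True, True)
        a = augment(v, flags, seed=11)
        b = augment(v, flags, seed=11)
        np.testing.assert_array_equal(a, b)
        c = augment(v, flags, seed=12)
        assert not np.array_equal(a, c)


class TestMixup:
    def test_endpoint_and_midpoint(self):
        xa, xb = np.zeros((2, 2)), np.ones((2, 2))
        ya, yb = np.eye(3)[[0, 1]], np.eye(3)[[2, 2]]
        x, y = mixup_batch(xa, ya, xb, yb, lam_mix=1.0)
        np.testing.assert_array_equal(x, xa)
        np.testing.assert_array_equal(y, ya)
        x, y = mixup_batch(xa, ya, xb, yb, lam_mix=0.5)
        np.testing.assert_allclose(x, 0.5)
        np.testing.assert_allclose(y.sum(axis=1), 1.0)

    def test_sampled_coefficient_in_unit_interval(self):
        xa = np.zeros((1,))
        xb = np.ones((1,))
        for seed in range(20):
            x, _ = mixup_batch(xa, np.eye(2)[[0]], xb, np.eye(2)[[1]], alpha=0.2, seed=seed)
            assert 0.0 <= x[0] <= 1.0


class TestAccumulationAndStages:
    def test_gradient_accumulation_equals_one_large_batch(self, tiny_X_y, small_model_config):
        X, y = tiny_X_y
        idx = np.r_[0:6, 10:15, 18:23]  # 6 NC, 5 MCI, 5 AD
        Xb, yb = X[idx], _one_hot(y[idx], 3)
        w = class_weights(y[idx], 3)

        def run(micro_batches):
            net = AttentionNet3D(small_model_config)
            opt = Adam(net.parameters(), lr=1e-3)
            accumulate_and_step(net, opt, micro_batches, w, 0.0, None)
            return net

        net_full = run([(Xb, yb)])
        net_micro = run([(Xb[i:i + 2], yb[i:i + 2]) for i in range(0, 16, 2)])
        for k in net_full.params:
            np.testing.assert_allclose(net_micro.params[k].data, net_full.params[k].data,
                                       rtol=1e-5, atol=1e-10)

    def test_recorded_total_equals_wce_plus_lam_sim(self, tiny_X_y, small_model_config):
        X, y = tiny_X_y
        rng = np.random.default_rng(0)
        priors = [ClassPrior(k, rng.random((16, 16, 16)), 1) for k in range(3)]
        est = AttentionGuidedClassifier(model_config=small_model_config, lam=0.01,
                                        priors=priors, epochs=1, micro_batch=2,
                                        accumulation_steps=2, random_state=0)
        est.fit(X, y)
        for rec in est.history_["steps"]:
            assert rec["total"] == pytest.approx(rec["wce"] + 0.01 * rec["sim"], abs=1e-9)

    def test_lam_zero_stage2_reproduces_stage1_step_for_step(self, tiny_X_y, small_model_config):
        X, y = tiny_X_y
        rng = np.random.default_rng(1)
        priors = [ClassPrior(k, rng.random((16, 16, 16)), 1) for k in range(3)]
        tc = TrainConfig(lam=0.0, epochs=2, micro_batch=2, accumulation_steps=2, seed=4)
        est1, h1 = train_stage1(X, y, small_model_config, tc)
        est2, h2 = train_stage2(X, y, priors, small_model_config, tc)
        assert len(h1["steps"]) == len(h2["steps"])
        for r1, r2 in zip(h1["steps"], h2["steps"]):
            assert r2["wce"] == pytest.approx(r1["wce"], abs=1e-9)
            assert r2["total"] == pytest.approx(r1["total"], abs=1e-9)
        for k in est1.net_.params:
            np.testing.assert_array_equal(est1.net_.params[k].data, est2.net_.params[k].data)

    def test_same_seed_gives_identical_history(self, tiny_X_y, small_model_config):
        X, y = tiny_X_y
        tc = TrainConfig(epochs=2, micro_batch=2, accumulation_steps=2, seed=9)
        _, h1 = train_stage1(X, y, small_model_config, tc)
        _, h2 = train_stage1(X, y, small_model_config, tc)
        assert h1 == h2

    def test_history_length_matches_epochs(self, trained_baseline):
        _, history = trained_baseline
        assert len(history["epochs"]) == 8

    def test_linearly_separable_toy_cohort_is_fit(self):
        """Two classes separated by a large uniform intensity offset."""
        rng = np.random.default_rng(5)
        n = 12
        X0 = rng.random((n, 8, 8, 8)) * 0.2
        X1 = rng.random((n, 8, 8, 8)) * 0.2 + 0.8
        X = np.concatenate([X0, X1])
        y = np.repeat([0, 1], n)
        cfg = ModelConfig(n_classes=2, encoder_channels=(4,), downsample_factor=2, seed=0)
        est = AttentionGuidedClassifier(model_config=cfg, epochs=20, micro_batch=4,
                                        accumulation_steps=1, learning_rate=3e-3,
                                        random_state=0)
        est.fit(X, y)
        assert (est.predict(X) == y).mean() >= 0.95

    def test_stage2_requires_all_priors_present(self, tiny_X_y, small_model_config):
        X, y = tiny_X_y
        priors = [ClassPrior(0, np.zeros((16, 16, 16)), 1), ClassPrior(1, None, 0),
                  ClassPrior(2, np.zeros((16, 16, 16)), 1)]
        with pytest.raises(ValueError, match="absent"):
            train_stage2(X, y, priors, small_model_config, TrainConfig(epochs=1))

    def test_estimator_is_sklearn_compatible(self, small_model_config):
        from sklearn.base import clone

        est = AttentionGuidedClassifier(model_config=small_model_config, lam=0.5,
                                        epochs=3, random_state=7)
        params = est.get_params()
        assert params["lam"] == 0.5 and params["random_state"] == 7
        cloned = clone(est)
        assert cloned.get_params()["lam"] == 0.5
        cloned.set_params(epochs=5)
        assert cloned.epochs == 5
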