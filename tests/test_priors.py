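"""Attribution correctness: exact Shapley axioms, expected gradients, priors."""

import numpy as np
import pytest

from neurodg import (AttributionConfig, ClassPrior, attribute, build_class_priors,
                     exact_shapley, resample_prior, scale_to_unit)
from neurodg.priors import resample_grid


class LinearScorer:
    """f_k(x) = w_k . x + b_k with exact input gradients."""

    def __init__(self, w, b=0.0):
        self.w = np.asarray(w, dtype=np.float64)
        self.b = b

    def score_and_grad(self, volume, target_class):
        return float((self.w * volume).sum() + self.b), self.w.copy()


class TestExactShapley:
    def test_additive_score_attributes_each_group_its_own_term(self):
        rng = np.random.default_rng(0)
        coef = rng.standard_normal(6)
        groups = [np.array([i]) for i in range(6)]
        x = rng.standard_normal(6)
        base = np.zeros(6)
        phi = exact_shapley(lambda z: float(coef @ z), x, base, groups)
        np.testing.assert_allclose(phi, coef * x, atol=1e-12)

    def test_symmetric_groups_receive_equal_attribution(self):
        # score depends only on the sum -> interchangeable features
        x = np.full(4, 2.0)
        phi = exact_shapley(lambda z: float(z.sum() ** 2), x, np.zeros(4),
                            [np.array([i]) for i in range(4)])
        np.testing.assert_allclose(phi, phi[0])

    @pytest.mark.parametrize("n_groups", [3, 7, 10])
    def test_efficiency_axiom_on_random_two_layer_scorers(self, n_groups):
        rng = np.random.default_rng(n_groups)
        for _ in range(10):
            w1 = rng.standard_normal((5, n_groups))
            w2 = rng.standard_normal(5)
            fn = lambda z: float(np.tanh(w1 @ z) @ w2)
            x = rng.standard_normal(n_groups)
            base = rng.standard_normal(n_groups)
            phi = exact_shapley(fn, x, base, [np.array([i]) for i in range(n_groups)])
            assert phi.sum() == pytest.approx(fn(x) - fn(base), abs=1e-9)

    def test_group_limit_enforced(self):
        with pytest.raises(ValueError, match="16"):
            exact_shapley(lambda z: 0.0, np.zeros(20), np.zeros(20),
                          [np.array([i]) for i in range(20)])


class TestExpectedGradients:
    def test_linear_model_closed_form_with_zero_background(self):
        rng = np.random.default_rng(1)
        w = rng.standard_normal((4, 4, 4))
        x = rng.random((4, 4, 4))
        cfg = AttributionConfig(n_draws=3, seed=0)
        attr = attribute(LinearScorer(w), x, 0, [np.zeros_like(x)], cfg)
        np.testing.assert_allclose(attr, w * x, atol=1e-12)

    def test_input_equal_to_only_background_attributes_zero(self):
        x = np.random.default_rng(2).random((3, 3, 3))
        cfg = AttributionConfig(n_draws=5, seed=1)
        attr = attribute(LinearScorer(np.ones_like(x)), x, 0, [x.copy()], cfg)
        np.testing.assert_allclose(attr, 0.0, atol=1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        w = rng.standard_normal((3, 3, 3))
        x = rng.random((3, 3, 3))
        bgs = [rng.random((3, 3, 3)) for _ in range(3)]
        cfg = AttributionConfig(n_draws=4, seed=9)
        a = attribute(LinearScorer(w), x, 0, bgs, cfg)
        b = attribute(LinearScorer(w), x, 0, bgs, cfg)
        np.testing.assert_array_equal(a, b)

    def test_matches_exact_shapley_on_small_nonlinear_scorer(self):
        """On an 8-voxel model the Monte-Carlo estimate approaches the exact
        Shapley values, and the completeness gap shrinks with n_draws.

        The estimator converges to the path-integral attribution, which
        coincides with subset-enumeration Shapley exactly for additive
        scorers and up to a curvature-controlled gap otherwise; a mildly
        nonlinear scorer keeps that gap inside the Monte-Carlo tolerance.
        """
        rng = np.random.default_rng(4)
        w1 = rng.standard_normal((6, 8)) * 0.25
        w2 = rng.standard_normal(6)

        class TanhScorer:
            def score_and_grad(self, volume, target_class):
                z = volume.ravel()
                h = np.tanh(w1 @ z)
                grad = ((1 - h**2) * w2) @ w1
                return float(h @ w2), grad.reshape(volume.shape)

        fn = lambda z: float(np.tanh(w1 @ z.ravel()) @ w2)
        x = rng.random((2, 2, 2))
        baseline = np.zeros((2, 2, 2))
        phi = exact_shapley(fn, x, baseline, [np.array([i]) for i in range(8)])

        gaps = []
        for n_draws in (64, 1024):
            cfg = AttributionConfig(n_draws=n_draws, seed=0)
            attr = attribute(TanhScorer(), x, 0, [baseline], cfg).ravel()
            gaps.append(np.abs(attr - phi).max())
        assert gaps[1] < gaps[0]          # error shrinks with more draws
        assert gaps[1] < 0.05             # and is small in absolute terms
        # completeness: attributions sum to f(x) - f(baseline) within MC tol
        assert attr.sum() == pytest.approx(fn(x) - fn(baseline), abs=0.05)


class _S:
    def __init__(self, v, l):
        self.volume, self.label = v, l


@pytest.fixture(scope="module")
def perfect_setup():
    """A linear scorer arranged to classify a 6-sample toy set perfectly."""
    rng = np.random.default_rng(5)
    shape = (3, 3, 3)

    class TwoClassModel:
        """Linear scorer on centered intensities: low volumes -> class 0."""

        class config:
            n_classes = 2

        def __init__(self):
            self.w = {0: -np.ones(shape), 1: np.ones(shape)}

        def predict_proba(self, X):
            logits = np.stack([(self.w[k] * (X - 0.5)).sum(axis=(1, 2, 3))
                               for k in (0, 1)], axis=1)
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            return e / e.sum(axis=1, keepdims=True)

        def score_and_grad(self, volume, k):
            return float((self.w[k] * (volume - 0.5)).sum()), self.w[k].copy()

    lows = [rng.random(shape) * 0.2 for _ in range(3)]
    highs = [rng.random(shape) * 0.2 + 0.8 for _ in range(3)]
    samples = [_S(v, 0) for v in lows] + [_S(v, 1) for v in highs]
    return TwoClassModel(), samples, lows


class TestClassPriors:
    def test_prior_is_direct_average_over_correct_predictions(self, perfect_setup):
        model, samples, lows = perfect_setup
        cfg = AttributionConfig(n_draws=2, seed=0)
        bg = [np.zeros((3, 3, 3))]
        priors = build_class_priors(model, samples, cfg, background=bg)
        for k in (0, 1):
            members = [s for s in samples if s.label == k]
            expected = np.mean(
                [attribute(model, s.volume, k, bg, cfg) for s in members], axis=0
            )
            np.testing.assert_allclose(priors[k].grid, expected, atol=1e-12)
            assert priors[k].n_samples_averaged == 3

    def test_priors_invariant_under_dataset_permutation(self, perfect_setup):
        model, samples, _ = perfect_setup
        cfg = AttributionConfig(n_draws=2, seed=0)
        bg = [np.zeros((3, 3, 3))]
        a = build_class_priors(model, samples, cfg, background=bg)
        b = build_class_priors(model, samples[::-1], cfg, background=bg)
        for pa, pb in zip(a, b):
            np.testing.assert_allclose(pa.grid, pb.grid, atol=1e-12)

    def test_class_with_no_correct_predictions_gets_absent_marker(self, perfect_setup):
        model, samples, lows = perfect_setup
        mislabeled = [_S(v, 1) for v in lows]  # model will predict 0, label 1
        correct = [s for s in samples if s.label == 0]
        priors = build_class_priors(model, correct + mislabeled,
                                    AttributionConfig(n_draws=1, seed=0),
                                    background=[np.zeros((3, 3, 3))])
        assert not priors[0].absent
        assert priors[1].absent and priors[1].n_samples_averaged == 0

    def test_no_correct_predictions_anywhere_is_hard_error(self, perfect_setup):
        model, samples, lows = perfect_setup
        flipped = [_S(s.volume, 1 - s.label) for s in samples]
        with pytest.raises(RuntimeError, match="no correct prediction"):
            build_class_priors(model, flipped, AttributionConfig(n_draws=1, seed=0),
                               background=[np.zeros((3, 3, 3))])


class TestScaleAndResample:
    def test_unit_scaling_preserves_sign_and_maps_peak_to_one(self):
        grid = np.array([[[1.0, -4.0], [2.0, 0.0]], [[0.5, -1.0], [3.0, -2.0]]])
        p = scale_to_unit(ClassPrior(2, grid, 5))
        assert p.scale == "unit"
        assert np.abs(p.grid).max() == pytest.approx(1.0)
        assert p.grid.min() >= -1.0 and p.grid.max() <= 1.0
        np.testing.assert_array_equal(np.sign(p.grid), np.sign(grid))
        # antisymmetric grid stays antisymmetric
        anti = np.stack([grid[0], -grid[0]])
        pa = scale_to_unit(ClassPrior(0, anti, 1))
        np.testing.assert_allclose(pa.grid[0], -pa.grid[1])

    def test_unit_scaling_preserves_magnitude_rank_order(self):
        rng = np.random.default_rng(8)
        grid = rng.standard_normal((4, 4, 4))
        p = scale_to_unit(ClassPrior(0, grid, 1))
        assert np.array_equal(np.argsort(np.abs(grid).ravel()),
                              np.argsort(np.abs(p.grid).ravel()))

    def test_all_zero_grid_returned_unchanged_with_warning_flag(self):
        p = scale_to_unit(ClassPrior(0, np.zeros((2, 2, 2)), 1))
        assert p.all_zero_warning
        np.testing.assert_array_equal(p.grid, 0.0)

    def test_resample_constant_and_identity(self):
        const = np.full((5, 5, 5), 3.7)
        out = resample_grid(const, (9, 3, 5))
        np.testing.assert_allclose(out, 3.7, atol=1e-12)
        same = resample_grid(const, (5, 5, 5))
        np.testing.assert_array_equal(same, const)

    def test_downsampled_linear_ramp_stays_linear(self):
        # ramp along axis 0 on 9 points -> 5 points: values 0, 2, 4, 6, 8
        ramp = np.broadcast_to(np.arange(9.0)[:, None, None], (9, 9, 9)).copy()
        out = resample_grid(ramp, (5, 5, 5))
        expected = np.broadcast_to(np.arange(0.0, 9.0, 2.0)[:, None, None], (5, 5, 5))
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_resample_prior_wraps_grid_resampling(self):
        p = ClassPrior(1, np.random.default_rng(0).random((4, 4, 4)), 2)
        q = resample_prior(p, (2, 2, 2))
        assert q.grid.shape == (2, 2, 2)
        assert q.class_id == 1 and q.n_samples_averaged == 2
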