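"""Loss functions against hand-computed values and brute-force oracles;
augmentation statistics; training-loop behavior."""

import numpy as np
import pytest

from ecgunet.model import UNet1d, UNetConfig
from ecgunet.training import (AugmentConfig, TrainConfig, augment,
                              composite_loss, composite_loss_grad, dice_loss,
                              focal_loss, train)

EPS = 1e-6


def brute_dice(probs, target, n_classes=3):
    """Literal per-class summation of the soft-dice formula."""
    total = 0.0
    for c in range(n_classes):
        inter = sum(p[c] for p, t in zip(probs, target) if t == c)
        psum = sum(p[c] for p in probs)
        gsum = sum(1 for t in target if t == c)
        total += 1.0 - (2.0 * inter + EPS) / (psum + gsum + EPS)
    return total / n_classes


def brute_focal(probs, target, alpha=(1.0, 1.0, 1.5), gamma=2.0):
    vals = []
    for p, t in zip(probs, target):
        pg = max(p[t], 1e-8)
        vals.append(-alpha[t] * (1 - pg) ** gamma * np.log(pg))
    return float(np.mean(vals))


def random_fixture(rng, L):
    z = rng.normal(size=(L, 3))
    p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    t = rng.integers(0, 3, size=L)
    return p, t


class TestDice:
    def test_perfect_prediction_near_zero(self):
        t = np.array([0, 1, 2, 1])
        p = np.eye(3)[t]
        assert dice_loss(p, t) < 1e-5

    def test_total_mismatch_near_one(self):
        t = np.array([0, 0, 1, 1, 2, 2])
        p = np.eye(3)[(t + 1) % 3]
        assert dice_loss(p, t) == pytest.approx(1.0, abs=1e-5)

    def test_hand_computed_uniform_case(self):
        # L=4, target (0,0,1,1), uniform probs: class-0 and class-1 dice
        # terms are 1 - (2*2/3)/(4/3+2) = 0.6; class-2 term -> 1; mean 11/15
        t = np.array([0, 0, 1, 1])
        p = np.full((4, 3), 1 / 3)
        assert dice_loss(p, t) == pytest.approx(11 / 15, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.full((4, 3), 1 / 3), np.zeros(5, dtype=int))

    def test_rows_must_be_stochastic(self):
        p = np.full((4, 3), 0.5)
        with pytest.raises(ValueError):
            dice_loss(p, np.zeros(4, dtype=int))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p, t = random_fixture(rng, int(rng.integers(4, 64)))
        assert dice_loss(p, t) == pytest.approx(brute_dice(p, t), abs=1e-9)

    def test_permutation_invariant(self, rng):
        p, t = random_fixture(rng, 32)
        perm = rng.permutation(32)
        assert dice_loss(p[perm], t[perm]) == pytest.approx(
            dice_loss(p, t), abs=1e-12)


class TestFocal:
    def test_perfect_prediction_zero(self):
        t = np.array([0, 1, 2])
        assert focal_loss(np.eye(3)[t], t) < 1e-12

    def test_gamma_zero_is_weighted_cross_entropy(self, rng):
        p, t = random_fixture(rng, 50)
        alpha = (1.0, 1.0, 1.5)
        fl = focal_loss(p, t, alpha, gamma=0.0)
        ce = np.mean([-alpha[ti] * np.log(pi[ti]) for pi, ti in zip(p, t)])
        assert fl == pytest.approx(ce, abs=1e-12)

    def test_hand_computed_single_pvc_sample(self):
        # p_true = 0.5, alpha 1.5, gamma 2 -> 1.5 * 0.25 * ln 2
        p = np.array([[0.25, 0.25, 0.5]])
        t = np.array([2])
        assert focal_loss(p, t) == pytest.approx(1.5 * 0.25 * np.log(2),
                                                 abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p, t = random_fixture(rng, int(rng.integers(4, 64)))
        assert focal_loss(p, t) == pytest.approx(brute_focal(p, t), abs=1e-9)

    def test_permutation_invariant(self, rng):
        p, t = random_fixture(rng, 32)
        perm = rng.permutation(32)
        assert focal_loss(p[perm], t[perm]) == pytest.approx(
            focal_loss(p, t), abs=1e-12)


class TestComposite:
    def test_equal_weighting(self, rng):
        p, t = random_fixture(rng, 40)
        expected = 0.5 * dice_loss(p, t) + 0.5 * focal_loss(p, t)
        assert composite_loss(p, t) == pytest.approx(expected, abs=1e-12)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            TrainConfig(dice_weight=0.7, focal_weight=0.5).validate()

    def test_gradient_matches_finite_difference(self):
        """d(composite)/d(logits) against central differences; the loss
        is smooth in the logits so this oracle is reliable."""
        rng = np.random.default_rng(0)
        cfg = TrainConfig()
        z = rng.normal(size=(1, 3, 12)).astype(np.float64)
        t = rng.integers(0, 3, size=(1, 12))
        total, _, _, dz = composite_loss_grad(z, t, cfg)
        for _ in range(12):
            idx = (0, rng.integers(0, 3), rng.integers(0, 12))
            eps = 1e-6
            zp, zm = z.copy(), z.copy()
            zp[idx] += eps
            zm[idx] -= eps
            lp = composite_loss_grad(zp, t, cfg)[0]
            lm = composite_loss_grad(zm, t, cfg)[0]
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(float(dz[idx]), rel=1e-4, abs=1e-9)

    def test_loss_value_consistent_with_public_functions(self, rng):
        z = rng.normal(size=(1, 3, 30))
        t = rng.integers(0, 3, size=(1, 30))
        total, dice, focal, _ = composite_loss_grad(z, t, TrainConfig())
        p = np.exp(z[0].T - z[0].T.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        assert dice == pytest.approx(dice_loss(p, t[0]), abs=1e-9)
        assert focal == pytest.approx(focal_loss(p, t[0]), abs=1e-9)
        assert total == pytest.approx(0.5 * dice + 0.5 * focal, abs=1e-12)


class TestAugment:
    def test_all_probabilities_zero_is_identity(self, rng):
        x = rng.normal(size=100)
        cfg = AugmentConfig(p_scale=0, p_offset=0, p_noise=0)
        assert np.array_equal(augment(x, cfg, rng), x)

    def test_seeded_reproducibility(self):
        x = np.random.default_rng(0).normal(size=200)
        a = augment(x, AugmentConfig(), np.random.default_rng(9))
        b = augment(x, AugmentConfig(), np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_scale_factor_statistics(self):
        # with p_scale=1 and no other transforms, recovered factors are
        # uniform on [0.6, 1.4]: mean 1.0 within 3 sigma
        rng = np.random.default_rng(7)
        x = np.ones(10)
        cfg = AugmentConfig(p_scale=1.0, p_offset=0.0, p_noise=0.0)
        factors = np.array([augment(x, cfg, rng)[0] for _ in range(10_000)])
        assert factors.min() >= 0.6 and factors.max() <= 1.4
        sd = (1.4 - 0.6) / np.sqrt(12)
        assert abs(factors.mean() - 1.0) < 3 * sd / np.sqrt(10_000)

    def test_invalid_config_rejected(self, rng):
        with pytest.raises(ValueError):
            augment(np.ones(10), AugmentConfig(p_scale=1.5), rng)


def _toy_problem(n_windows=6, L=512, seed=0):
    """Tiny learnable segmentation task: bumps on a flat background."""
    rng = np.random.default_rng(seed)
    w = np.zeros((n_windows, L), dtype=np.float32)
    m = np.zeros((n_windows, L), dtype=np.int8)
    for i in range(n_windows):
        for center in range(60, L - 60, 120):
            cls = 2 if rng.random() < 0.4 else 1
            amp = -1.0 if cls == 2 else 1.0
            w[i, center - 5:center + 5] += amp
            m[i, center - 12:center + 13] = cls
        w[i] += rng.normal(scale=0.05, size=L).astype(np.float32)
    return w, m


def _tiny_model(seed=0):
    return UNet1d(UNetConfig(depth=2, base_filters=4, min_input_len=64,
                             seed=seed))


class TestTrainLoop:
    def test_loss_decreases_on_learnable_data(self):
        w, m = _toy_problem()
        model = _tiny_model()
        hist = train(model, w, m,
                     TrainConfig(epochs=5, batch_size=3, seed=0))
        assert hist[-1]["loss"] < hist[0]["loss"]

    def test_same_seed_identical_history(self):
        w, m = _toy_problem()
        h1 = train(_tiny_model(1), w, m,
                   TrainConfig(epochs=2, batch_size=3, seed=5))
        h2 = train(_tiny_model(1), w, m,
                   TrainConfig(epochs=2, batch_size=3, seed=5))
        assert h1 == h2

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        w, m = _toy_problem()
        model = _tiny_model()
        before = [p.copy() for p in model.parameters()]
        train(model, w, m, TrainConfig(epochs=1, batch_size=3,
                                       learning_rate=0.0, seed=0))
        for b, p in zip(before, model.parameters()):
            assert np.array_equal(b, p)

    def test_no_pvc_windows_warns(self):
        w, m = _toy_problem()
        m[m == 2] = 1
        with pytest.warns(UserWarning, match="no PVC"):
            train(_tiny_model(), w, m,
                  TrainConfig(epochs=1, batch_size=3, seed=0))
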