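"""Loss-formula oracles, learning-rate schedule, engine gradients, and
fit-loop sanity on separable data."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from patchrefine.models import build_refinenet
from patchrefine.nn import NumpyNet, softmax
from patchrefine.training import LossInputs, TrainConfig, fit, lr_at, softmax_loss


def naive_softmax_loss(scores, labels):
    """Direct, unstabilized evaluation of the loss formula."""
    total = 0.0
    for f, y in zip(scores, labels):
        total += -np.log(np.exp(f[y]) / np.exp(f).sum())
    return total / len(labels)


class TestSoftmaxLoss:
    def test_uniform_scores_give_log_k(self):
        loss = softmax_loss(LossInputs(np.zeros((1, 4)), [0]))
        assert loss == pytest.approx(np.log(4), abs=1e-12)

    def test_two_class_hand_value(self):
        loss = softmax_loss(LossInputs([[2.0, 0.0]], [0]))
        assert loss == pytest.approx(np.log(1 + np.exp(-2)), abs=1e-12)

    def test_loss_vanishes_as_margin_grows(self):
        losses = [
            softmax_loss(LossInputs([[m, 0.0, 0.0]], [0])) for m in (1, 5, 10, 30)
        ]
        assert all(a > b for a, b in zip(losses, losses[1:]))
        assert losses[-1] < 1e-10

    def test_matches_naive_evaluation(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n, k = int(rng.integers(1, 8)), int(rng.integers(2, 6))
            scores = rng.normal(0, 3, (n, k))
            labels = rng.integers(0, k, n)
            assert softmax_loss(LossInputs(scores, labels)) == pytest.approx(
                naive_softmax_loss(scores, labels), abs=1e-10
            )

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-50, 50))
    def test_shift_invariance(self, shift):
        rng = np.random.default_rng(3)
        scores = rng.normal(0, 2, (5, 4))
        labels = rng.integers(0, 4, 5)
        a = softmax_loss(LossInputs(scores, labels))
        b = softmax_loss(LossInputs(scores + shift, labels))
        assert a == pytest.approx(b, abs=1e-9)

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            LossInputs(np.zeros((2, 3)), [0, 3])

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            LossInputs([[np.inf, 0.0]], [0])


class TestSchedule:
    @pytest.mark.parametrize(
        "stage,lr", [(0, 0.05), (1, 0.01), (2, 1e-3), (3, 1e-4), (5, 1e-6)]
    )
    def test_staged_decay(self, stage, lr):
        assert lr_at(stage, TrainConfig()) == pytest.approx(lr)

    def test_rates_must_decrease(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_stages=(0.01, 0.05))


class TestEngineGradients:
    def test_backprop_matches_finite_differences(self):
        """Central differences at eps=5e-3 (below the PReLU/maxpool kink
        scale, above float32 noise) agree with analytic gradients."""
        net = NumpyNet(build_refinenet(3, (32, 32)), seed=1)
        rng = np.random.default_rng(3)
        X = rng.random((4, 3, 32, 32), dtype=np.float32)
        y = np.array([0, 1, 2, 1])

        def loss_of():
            p = softmax(net.forward(X, train=True).astype(np.float64))
            return float(-np.log(p[np.arange(4), y]).mean())

        for p in net.params():
            p.grad[...] = 0.0
        probs = softmax(net.forward(X, train=True))
        d = probs.copy()
        d[np.arange(4), y] -= 1
        net.backward(d / 4)

        check_rng = np.random.default_rng(5)
        params = net.params()
        checked = passed = 0
        for pi in (0, 2, 12, 20, len(params) - 2, len(params) - 1):
            p = params[pi]
            flat = p.value.reshape(-1)
            idx = int(check_rng.integers(0, flat.size))
            ana = float(p.grad.reshape(-1)[idx])
            old = flat[idx]
            ok = False
            for eps in (5e-3, 2e-3, 1e-2):  # straddle kink/float32 noise scales
                flat[idx] = old + eps
                lp = loss_of()
                flat[idx] = old - eps
                lm = loss_of()
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                if abs(num - ana) <= 0.08 * max(abs(num), abs(ana)) + 2e-4:
                    ok = True
                    break
            checked += 1
            passed += ok
        assert passed >= checked - 1, f"{passed}/{checked} gradient probes agreed"


class TestFit:
    @staticmethod
    def toy_data(n, seed, bright=170, dark=80):
        """Linearly separable two-texture toy: bright vs dark noisy squares."""
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        means = np.where(y == 0, bright, dark).astype(np.float32)
        X = rng.normal(means[:, None, None, None], 25, (n, 3, 32, 32))
        X = (X.astype(np.float32) / 255.0 - 0.5).astype(np.float32)
        return X, y

    def test_separable_data_is_learnable(self):
        Xtr, ytr = self.toy_data(256, 0)
        Xv, yv = self.toy_data(128, 1)
        cfg = TrainConfig(lr_stages=(0.05, 0.01), epochs_per_stage=2, max_epochs=4,
                          seed=0, early_stop_patience=None)
        net, hist = fit(build_refinenet(2, (32, 32)), (Xtr, ytr), (Xv, yv), cfg)
        assert hist[-1]["val_aca"] >= 0.95

    def test_loss_decreases_over_epochs(self):
        Xtr, ytr = self.toy_data(256, 2)
        cfg = TrainConfig(lr_stages=(0.05, 0.01), epochs_per_stage=2, max_epochs=4,
                          seed=0, early_stop_patience=None)
        _, hist = fit(build_refinenet(2, (32, 32)), (Xtr, ytr), None, cfg)
        assert hist[-1]["loss"] < hist[0]["loss"]

    def test_untrained_model_is_at_chance(self):
        rng = np.random.default_rng(9)
        X = rng.random((200, 3, 32, 32), dtype=np.float32) - 0.5
        y = rng.integers(0, 4, 200)
        net = NumpyNet(build_refinenet(4, (32, 32)), seed=4)
        acc = float((net.predict_proba(X).argmax(axis=1) == y).mean())
        assert 0.10 <= acc <= 0.45  # ~1/K for K=4

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            fit(build_refinenet(2, (32, 32)),
                (np.empty((0, 3, 32, 32), dtype=np.float32), np.empty(0, dtype=int)),
                None, TrainConfig())

    def test_label_out_of_model_range_rejected(self):
        X = np.zeros((8, 3, 32, 32), dtype=np.float32)
        y = np.full(8, 5)
        with pytest.raises(ValueError):
            fit(build_refinenet(2, (32, 32)), (X, y), None, TrainConfig())
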