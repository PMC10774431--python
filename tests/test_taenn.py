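"""Gated recurrent classifier: schedule, activation, gradients, training."""

import math

import numpy as np
import pytest

from szdetect.signal_io import LabeledDataset
from szdetect.taenn import (
    TAENNHyper,
    _loss_and_grads,
    init_params,
    load_model,
    lr_schedule,
    penalized_tanh,
    save_model,
    taenn_forward,
    taenn_predict,
    taenn_train,
)


class TestLRSchedule:
    def test_starts_at_max_learning_rate(self):
        hyper = TAENNHyper(theta=0.01, rho=1e-4, vartheta=1e-2, epochs=100)
        assert lr_schedule(0, hyper) == pytest.approx(1e-2, rel=1e-15)

    def test_ends_at_min_rate_without_decay(self):
        hyper = TAENNHyper(theta=0.0, rho=1e-4, vartheta=1e-2, epochs=100)
        assert lr_schedule(100, hyper) == pytest.approx(1e-4, rel=1e-15)

    def test_decayed_endpoint_hand_value(self):
        hyper = TAENNHyper(theta=0.01, rho=1e-4, vartheta=1e-2, epochs=100)
        assert lr_schedule(100, hyper) == pytest.approx(math.exp(-1) * 1e-4,
                                                        abs=1e-8)

    def test_never_exceeds_max_rate(self):
        hyper = TAENNHyper(theta=0.05, rho=1e-4, vartheta=1e-2, epochs=50)
        assert all(lr_schedule(ep, hyper) <= hyper.vartheta + 1e-18
                   for ep in range(51))

    def test_epoch_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(101, TAENNHyper(epochs=100))


class TestPenalizedTanh:
    def test_positive_branch_ignores_gamma(self):
        v, dh, dg = penalized_tanh(np.array(1.0), np.array(0.25))
        assert v == pytest.approx(math.tanh(1.0))
        assert dg == 0.0

    def test_continuous_at_zero(self):
        v, _, _ = penalized_tanh(np.array(0.0), np.array(7.0))
        assert v == 0.0

    def test_negative_branch_values_and_gradients(self):
        v, dh, dg = penalized_tanh(np.array(-1.0), np.array(0.25))
        assert v == pytest.approx(0.25 * math.tanh(-1.0), abs=1e-12)
        assert dg == pytest.approx(math.tanh(-1.0), abs=1e-12)
        # central finite differences on both partials
        eps = 1e-6
        vp, _, _ = penalized_tanh(np.array(-1.0 + eps), np.array(0.25))
        vm, _, _ = penalized_tanh(np.array(-1.0 - eps), np.array(0.25))
        assert dh == pytest.approx((vp - vm) / (2 * eps), abs=1e-6)
        gp, _, _ = penalized_tanh(np.array(-1.0), np.array(0.25 + eps))
        gm, _, _ = penalized_tanh(np.array(-1.0), np.array(0.25 - eps))
        assert dg == pytest.approx((gp - gm) / (2 * eps), abs=1e-6)


class TestForward:
    def test_zero_parameters_give_uniform_probabilities(self):
        params = init_params(3, 4, 2, np.random.default_rng(0))
        for name in params.names():
            getattr(params, name)[...] = 0.0
        probs, _ = taenn_forward(np.zeros((2, 3)), params, TAENNHyper())
        np.testing.assert_allclose(probs, [0.5, 0.5])

    def test_gamma_one_reduces_to_plain_tanh(self):
        rng = np.random.default_rng(1)
        params = init_params(3, 4, 2, rng)
        params.gamma[...] = 1.0
        x = rng.standard_normal((2, 3))
        probs, cache = taenn_forward(x, params, TAENNHyper())
        for c, fc in zip(cache["c"], cache["fc"]):
            np.testing.assert_allclose(fc, np.tanh(c), atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        params = init_params(3, 4, 2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            taenn_forward(np.zeros((2, 5)), params, TAENNHyper())

    def test_eval_mode_deterministic_and_rng_free(self):
        rng = np.random.default_rng(2)
        params = init_params(3, 4, 2, rng)
        x = rng.standard_normal((5, 2, 3))
        p1, _ = taenn_forward(x, params, TAENNHyper(), mode="eval")
        p2, _ = taenn_forward(x, params, TAENNHyper(), mode="eval")
        np.testing.assert_array_equal(p1, p2)


class TestGradients:
    @pytest.mark.parametrize("seed", range(10))
    def test_analytic_gradients_match_finite_differences(self, seed):
        """Full-parameter BPTT check, including the learnable slopes."""
        rng = np.random.default_rng(seed)
        d, H, C, K, B = 3, 4, 2, 2, 5
        params = init_params(d, H, C, rng)
        X = rng.standard_normal((B, K, d))
        y = rng.integers(0, C, B)
        hyper = TAENNHyper(hidden_size=H, dropout_rate=0.0, l1_lambda=1e-3,
                           seed=seed)
        _, grads, _ = _loss_and_grads(X, y, params, hyper, None)
        eps = 1e-6
        for name in params.names():
            arr = getattr(params, name)
            flat_idx = np.unravel_index(
                np.random.default_rng(seed).choice(arr.size, size=min(arr.size, 4),
                                                   replace=False), arr.shape)
            for ix in zip(*[np.atleast_1d(a) for a in flat_idx]):
                old = arr[ix]
                arr[ix] = old + eps
                lp, _, _ = _loss_and_grads(X, y, params, hyper, None)
                arr[ix] = old - eps
                lm, _, _ = _loss_and_grads(X, y, params, hyper, None)
                arr[ix] = old
                fd = (lp - lm) / (2 * eps)
                g = grads[name][ix]
                assert abs(fd - g) <= 1e-4 * max(1.0, abs(fd), abs(g)), \
                    f"{name}[{ix}]: analytic {g} vs numeric {fd}"


def _separable_dataset(n=400, d=6, gap=2.0, seed=1):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    X[y == 1] += gap
    return LabeledDataset([(X[i], "ab"[y[i]]) for i in range(n)]), X, y


class TestTraining:
    def test_learns_separable_classes(self):
        ds, X, y = _separable_dataset()
        train = LabeledDataset(ds.instances[:160] + ds.instances[200:360],
                               class_names=ds.class_names)
        model = taenn_train(train, TAENNHyper(seed=3))
        held = ds.instances[160:200] + ds.instances[360:]
        preds, _ = taenn_predict(model, [x for x, _ in held])
        acc = np.mean([p == lab for p, (_, lab) in zip(preds, held)])
        assert acc >= 0.95

    def test_bit_identical_given_seed(self):
        ds, _, _ = _separable_dataset(n=60)
        a = taenn_train(ds, TAENNHyper(seed=9, epochs=20))
        b = taenn_train(ds, TAENNHyper(seed=9, epochs=20))
        assert a.history == b.history
        for name in a.params.names():
            np.testing.assert_array_equal(getattr(a.params, name),
                                          getattr(b.params, name))

    def test_loss_moving_average_decreases(self):
        ds, _, _ = _separable_dataset()
        model = taenn_train(ds, TAENNHyper(seed=3))
        loss = np.array(model.history["loss"])
        ma = np.convolve(loss, np.ones(10) / 10, mode="valid")
        assert np.all(np.diff(ma[:41]) <= 1e-9)

    def test_history_lr_matches_schedule_exactly(self):
        ds, _, _ = _separable_dataset(n=60)
        hyper = TAENNHyper(seed=0, epochs=15)
        model = taenn_train(ds, hyper)
        assert model.history["lr"] == [lr_schedule(ep, hyper) for ep in range(15)]

    def test_l1_regularization_shrinks_weights(self):
        ds, _, _ = _separable_dataset(n=100)
        weight_names = ("C_i", "U_p", "W_mi", "W_mh", "W_oi", "W_ho", "W_om",
                        "W_out")

        def l1(model):
            return sum(np.abs(getattr(model.params, n)).sum()
                       for n in weight_names)

        free = taenn_train(ds, TAENNHyper(seed=4, l1_lambda=0.0))
        penalized = taenn_train(ds, TAENNHyper(seed=4, l1_lambda=1.0))
        assert l1(penalized) < l1(free)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        ds = LabeledDataset([(rng.standard_normal(4), "a") for _ in range(10)])
        with pytest.raises(ValueError):
            taenn_train(ds, TAENNHyper(seed=0, epochs=2))


class TestPredict:
    def test_probabilities_normalized_and_labels_known(self):
        ds, X, y = _separable_dataset(n=80)
        model = taenn_train(ds, TAENNHyper(seed=1, epochs=20))
        labels, probs = taenn_predict(model, list(X))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert set(labels) <= set(model.class_names)

    def test_prediction_is_argmax_of_forward(self):
        ds, X, _ = _separable_dataset(n=80)
        model = taenn_train(ds, TAENNHyper(seed=1, epochs=20))
        labels, probs = taenn_predict(model, list(X))
        assert labels == [model.class_names[i] for i in probs.argmax(axis=1)]

    def test_dimension_mismatch_rejected(self):
        ds, X, _ = _separable_dataset(n=40)
        model = taenn_train(ds, TAENNHyper(seed=1, epochs=5))
        with pytest.raises(ValueError):
            taenn_predict(model, [np.zeros(9)])


class TestSerialization:
    def test_save_load_bit_exact(self, tmp_path):
        ds, X, _ = _separable_dataset(n=60)
        model = taenn_train(ds, TAENNHyper(seed=2, epochs=10))
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        for name in model.params.names():
            np.testing.assert_array_equal(getattr(model.params, name),
                                          getattr(back.params, name))
        labels_a, probs_a = taenn_predict(model, list(X))
        labels_b, probs_b = taenn_predict(back, list(X))
        assert labels_a == labels_b
        np.testing.assert_array_equal(probs_a, probs_b)
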