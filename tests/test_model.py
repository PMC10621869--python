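"""MLP forward/backward, the Adam recursion, and training behavior."""

import numpy as np
import pytest

from wemd_apnea.model import (AdamState, MlpConfig, MlpModel, adam_step,
                              forward, predict, train)
from wemd_apnea.model import _backward


def _scalar_model(w0=0.0, **cfg_kw):
    cfg = MlpConfig(hidden_sizes=(), standardize=False, **cfg_kw)
    return MlpModel(weights=[np.array([[float(w0)]])],
                    biases=[np.zeros(1)], config=cfg)


def _reference_adam(grad_seq, w0=0.0, lr=0.01, b1=0.9, b2=0.999, eps=1e-8):
    """Independent scalar Adam recursion, plain Python floats."""
    w, v, s = float(w0), 0.0, 0.0
    history = []
    for t, g in enumerate(grad_seq, start=1):
        s = b2 * s + (1 - b2) * g * g
        v = b1 * v + (1 - b1) * g
        s_hat = s / (1 - b2**t)
        v_hat = v / (1 - b1**t)
        w -= lr * v_hat / (s_hat**0.5 + eps)
        history.append(w)
    return history


def test_forward_scores_sum_to_one(rng):
    cfg = MlpConfig(seed=0)
    X = rng.normal(size=(7, 15))
    model, _ = train(rng.normal(size=(10, 15)),
                     np.array([0] * 5 + [1] * 5),
                     MlpConfig(epochs=1, seed=0))
    proba = forward(model, X)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)


def test_zero_network_gives_uniform_scores():
    model = MlpModel(weights=[np.zeros((15, 2))], biases=[np.zeros(2)],
                     config=MlpConfig(hidden_sizes=(), standardize=False))
    proba = forward(model, np.ones((3, 15)))
    np.testing.assert_allclose(proba, 0.5)


def test_shape_mismatch_rejected():
    model = _scalar_model()
    with pytest.raises(ValueError):
        forward(model, np.ones((2, 3)))


def test_backprop_matches_finite_differences(rng):
    """Central-difference check of every weight and bias gradient."""
    cfg = MlpConfig(hidden_sizes=(4,), seed=1, standardize=False)
    X = rng.normal(size=(3, 5))
    y_onehot = np.eye(2)[[0, 1, 0]]
    model, _ = train(rng.normal(size=(6, 5)), np.array([0, 0, 0, 1, 1, 1]),
                     MlpConfig(hidden_sizes=(4,), epochs=1, seed=1,
                               standardize=False))

    def loss():
        p = np.clip(forward(model, X), 1e-12, 1.0)
        return float(-np.mean(np.sum(y_onehot * np.log(p), axis=1)))

    _, cache = forward(model, X, return_cache=True)
    dw, db = _backward(model, cache, y_onehot)
    h = 1e-6
    for params, grads in ((model.weights, dw), (model.biases, db)):
        for p, g in zip(params, grads):
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = p[idx]
                p[idx] = orig + h
                up = loss()
                p[idx] = orig - h
                down = loss()
                p[idx] = orig
                numeric = (up - down) / (2 * h)
                assert g[idx] == pytest.approx(numeric, rel=1e-5, abs=1e-7)


def test_adam_zero_gradient_is_fixed_point():
    model = _scalar_model(w0=1.5)
    state = AdamState.zeros_like(model)
    adam_step(model, ([np.zeros((1, 1))], [np.zeros(1)]), state)
    assert model.weights[0][0, 0] == 1.5


def test_adam_first_step_magnitude_is_learning_rate():
    """At t=1 the corrected moments cancel |g|, leaving ~alpha*sign(g)."""
    model = _scalar_model()
    state = AdamState.zeros_like(model)
    adam_step(model, ([np.array([[0.37]])], [np.zeros(1)]), state)
    assert abs(model.weights[0][0, 0]) == pytest.approx(0.01, rel=1e-6)
    assert model.weights[0][0, 0] < 0


def test_adam_matches_scalar_reference_over_100_steps(rng):
    grads = rng.normal(size=100)
    model = _scalar_model(w0=0.2)
    state = AdamState.zeros_like(model)
    got = []
    for g in grads:
        adam_step(model, ([np.array([[g]])], [np.zeros(1)]), state)
        got.append(model.weights[0][0, 0])
    expected = _reference_adam(grads, w0=0.2)
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_adam_minimizes_scalar_quadratic():
    """f(w) = (w-3)^2 from w=0 reaches |w-3| < 1e-2 within 2000 steps."""
    model = _scalar_model(w0=0.0)
    state = AdamState.zeros_like(model)
    for _ in range(2000):
        w = model.weights[0][0, 0]
        g = 2.0 * (w - 3.0)
        adam_step(model, ([np.array([[g]])], [np.zeros(1)]), state)
    assert abs(model.weights[0][0, 0] - 3.0) < 1e-2


def test_adam_nonfinite_gradient_rejected():
    model = _scalar_model()
    state = AdamState.zeros_like(model)
    with pytest.raises(ValueError):
        adam_step(model, ([np.array([[np.nan]])], [np.zeros(1)]), state)


def test_zero_learning_rate_never_moves_parameters(rng):
    model = _scalar_model(w0=0.7, learning_rate=0.0)
    state = AdamState.zeros_like(model)
    for g in rng.normal(size=50):
        adam_step(model, ([np.array([[g]])], [np.zeros(1)]), state)
    assert model.weights[0][0, 0] == 0.7


def test_literal_bias_correction_variant_differs():
    grads = [0.5, -0.2, 0.3]
    outs = []
    for literal in (False, True):
        model = _scalar_model(literal_bias_correction=literal)
        state = AdamState.zeros_like(model)
        for g in grads:
            adam_step(model, ([np.array([[g]])], [np.zeros(1)]), state)
        outs.append(model.weights[0][0, 0])
    assert outs[0] != outs[1]


# ---------------------------------------------------------------- training

def _blobs(rng, n=100, sep=6.0):
    X = np.vstack([rng.normal(0.0, 1.0, size=(n // 2, 2)),
                   rng.normal(sep, 1.0, size=(n // 2, 2))])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, y


def test_separable_blobs_reach_perfect_training_accuracy(rng):
    X, y = _blobs(rng)
    model, history = train(X, y, MlpConfig(epochs=100, seed=3))
    assert np.mean(predict(model, X) == y) == 1.0
    assert history[-1] < history[0]


def test_xor_learned_with_one_hidden_layer(rng):
    base = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    X = np.tile(base, (50, 1)) + rng.normal(0, 0.05, size=(200, 2))
    y = np.array([0, 1, 1, 0] * 50)
    model, _ = train(X, y, MlpConfig(hidden_sizes=(8,), epochs=300, seed=5))
    assert np.mean(predict(model, X) == y) >= 0.95


def test_training_deterministic_given_seed(rng):
    X, y = _blobs(rng)
    cfg = MlpConfig(epochs=20, seed=9)
    _, h1 = train(X, y, cfg)
    _, h2 = train(X, y, cfg)
    assert h1 == h2


def test_single_class_input_rejected(rng):
    X = rng.normal(size=(10, 2))
    with pytest.raises(ValueError):
        train(X, np.zeros(10), MlpConfig(epochs=1))


def test_prediction_tie_breaks_toward_first_class():
    model = MlpModel(weights=[np.zeros((2, 2))], biases=[np.zeros(2)],
                     config=MlpConfig(hidden_sizes=(), standardize=False),
                     classes=["neg", "pos"])
    assert predict(model, np.ones((1, 2)))[0] == "neg"


def test_model_save_load_round_trip(tmp_path, rng):
    X, y = _blobs(rng)
    model, _ = train(X, y, MlpConfig(epochs=10, seed=2))
    path = tmp_path / "model.json"
    model.save(path)
    back = MlpModel.load(path)
    np.testing.assert_allclose(forward(back, X), forward(model, X))
    assert back.classes == model.classes
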