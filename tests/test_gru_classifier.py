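"""GRU cell semantics, analytic-gradient verification against finite
differences, training-loop contracts, and map prediction."""

import dataclasses

import numpy as np
import pytest

from ricestress.gru_classifier import (
    NODATA,
    PARAM_NAMES,
    GRUModel,
    GRUWeights,
    TrainConfig,
    expected_parameter_count,
    forward,
    gru_cell_step,
    loss_and_gradients,
    predict_map,
    train,
)


def random_weights(rng, d=3, h=4, inner=3, k=3, scale=0.5):
    return GRUWeights.init(d, h, inner, k, rng, scale=scale)


def test_zero_weights_halve_previous_state():
    """sigma(0) = 0.5 and tanh(0) = 0, so h_t = 0.5 * h_prev."""
    w = GRUWeights.zeros(3, 4, 2, 3)
    rng = np.random.default_rng(0)
    x = rng.normal(size=(5, 3))
    h_prev = rng.normal(size=(5, 4))
    np.testing.assert_allclose(gru_cell_step(x, h_prev, w), 0.5 * h_prev)


def test_closed_reset_gate_discards_history():
    """br -> -inf forces R_t -> 0: the candidate sees no previous state."""
    rng = np.random.default_rng(1)
    w = random_weights(rng)
    w.br[...] = -1e9
    w.bz[...] = -1e9  # open (1 - Z_t) so h_t equals the candidate
    x = rng.normal(size=(2, 3))
    h_prev = rng.normal(size=(2, 4))
    got = gru_cell_step(x, h_prev, w)
    np.testing.assert_allclose(got, np.tanh(x @ w.Wxh + w.bh), atol=1e-12)


def test_gate_ranges_and_convex_combination_boundedness():
    rng = np.random.default_rng(2)
    for _ in range(10):
        w = random_weights(rng, scale=2.0)
        x = rng.normal(size=(4, 3))
        h = rng.uniform(-1, 1, size=(4, 4))
        for _ in range(7):
            h = gru_cell_step(x, h, w)
            assert (np.abs(h) <= 1.0 + 1e-12).all()


def test_analytic_gradients_match_finite_differences():
    """Central finite differences over every parameter entry on 20 random
    small instances (d=3, h=4, T=5), relative error < 1e-4."""
    rng = np.random.default_rng(3)
    eps = 1e-5
    for _ in range(20):
        w = random_weights(rng)
        seq = rng.normal(size=(2, 5, 3))
        y = rng.integers(0, 3, size=2)
        _, g = loss_and_gradients(seq, y, w)
        for name in PARAM_NAMES:
            arr, grad = getattr(w, name), getattr(g, name)
            for idx in np.ndindex(arr.shape):
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _ = loss_and_gradients(seq, y, w)
                arr[idx] = orig - eps
                lm, _ = loss_and_gradients(seq, y, w)
                arr[idx] = orig
                num = (lp - lm) / (2 * eps)
                denom = max(abs(num), abs(grad[idx]), 1e-6)
                assert abs(num - grad[idx]) / denom < 1e-4, (name, idx)


def test_forward_probabilities_normalized_and_deterministic():
    rng = np.random.default_rng(4)
    w = random_weights(rng, d=8, h=6, inner=3)
    model = GRUModel(weights=w, config=TrainConfig(hidden_size=6, fc_size=3))
    seq = rng.normal(size=(10, 7, 8))
    p = forward(seq, model)
    assert (p >= 0).all()
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
    np.testing.assert_array_equal(p[0], forward(seq[0], model)[0])


def test_zero_dense_head_gives_uniform_probabilities():
    rng = np.random.default_rng(5)
    w = random_weights(rng, d=8, h=6, inner=3)
    w.W1[...] = w.b1[...] = w.W2[...] = w.b2[...] = 0.0
    model = GRUModel(weights=w, config=TrainConfig(hidden_size=6, fc_size=3))
    p = forward(rng.normal(size=(4, 5, 8)), model)
    np.testing.assert_allclose(p, 1.0 / 3.0, atol=1e-12)


def test_empty_sequence_rejected():
    rng = np.random.default_rng(6)
    w = random_weights(rng, d=8, h=6, inner=3)
    model = GRUModel(weights=w, config=TrainConfig(hidden_size=6, fc_size=3))
    with pytest.raises(ValueError):
        forward(np.zeros((2, 0, 8)), model)


def test_parameter_count_closed_form():
    d, h, inner, k = 8, 256, 128, 3
    w = GRUWeights.zeros(d, h, inner, k)
    assert w.n_parameters() == expected_parameter_count(d, h, inner, k)
    assert expected_parameter_count(8, 256, 128, 3) == (
        3 * (8 * 256 + 256 * 256 + 256) + (256 * 128 + 128) + (128 * 3 + 3)
    )


def _toy_dataset(rng, n=40, T=6, d=8):
    seq = rng.normal(size=(n, T, d))
    labels = rng.integers(0, 3, size=n)
    seq[labels == 1] += 2.0
    seq[labels == 2] -= 2.0
    return seq, labels


def test_zero_learning_rate_leaves_weights_unchanged():
    rng = np.random.default_rng(7)
    seq, labels = _toy_dataset(rng)
    cfg = TrainConfig(hidden_size=5, fc_size=3, max_epochs=2,
                      learning_rate=0.0, seed=1)
    model, _ = train(seq[:30], labels[:30], seq[30:], labels[30:], cfg)
    init = GRUWeights.init(8, 5, 3, 3, np.random.default_rng(1))
    for name in PARAM_NAMES:
        np.testing.assert_array_equal(getattr(model.weights, name), getattr(init, name))


def test_training_is_deterministic_and_loss_decreases():
    rng = np.random.default_rng(8)
    seq, labels = _toy_dataset(rng, n=60)
    cfg = TrainConfig(hidden_size=8, fc_size=4, batch_size=8,
                      learning_rate=3e-3, max_epochs=10, patience=10, seed=2)
    m1, h1 = train(seq[:45], labels[:45], seq[45:], labels[45:], cfg)
    m2, h2 = train(seq[:45], labels[:45], seq[45:], labels[45:], cfg)
    assert h1.train_loss == h2.train_loss
    assert h1.test_accuracy == h2.test_accuracy
    for name in PARAM_NAMES:
        np.testing.assert_array_equal(getattr(m1.weights, name),
                                      getattr(m2.weights, name))
    assert h1.train_loss[-1] <= h1.train_loss[0]
    assert h1.n_epochs == len(h1.test_loss) == len(h1.train_accuracy)


def test_predict_map_grid_nodata_and_tiebreak():
    rng = np.random.default_rng(9)
    w = random_weights(rng, d=8, h=6, inner=3)
    model = GRUModel(weights=w, config=TrainConfig(hidden_size=6, fc_size=3))
    seq = rng.normal(size=(3, 5, 8))
    coords = np.array([[0, 0], [1, 2], [3, 3]])
    out = predict_map(model, seq, coords, (4, 4))
    assert out.shape == (4, 4)
    assert (out != NODATA).sum() == 3
    assert out[2, 2] == NODATA
    with pytest.raises(ValueError):
        predict_map(model, rng.normal(size=(3, 5, 5)), coords, (4, 4))
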