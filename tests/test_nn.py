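"""Engine-level checks: shapes, parameter counts, gradients, optimizer."""

import numpy as np
import pytest

from dynsig import nn
from dynsig.nnbench import ClassifierConfig, build_cnn, build_lstm


class _NullAdam(nn.Adam):
    """Adam with lr=0: computes/commits nothing, but train_step still stores grads."""

    def __init__(self):
        super().__init__(lr=0.0)


def _numeric_grad(network, x, t, param, idx, eps=1e-6):
    opt = _NullAdam()
    param[idx] += eps
    up, _ = network.train_step(x, t, opt, np.random.default_rng(0))
    param[idx] -= 2 * eps
    down, _ = network.train_step(x, t, opt, np.random.default_rng(0))
    param[idx] += eps
    return (up - down) / (2 * eps)


def _check_grads(network, x, t, atol=1e-7, rtol=1e-4):
    opt = _NullAdam()
    rng = np.random.default_rng(0)
    network.train_step(x, t, opt, rng)  # populate analytic grads
    analytic = [g.copy() for layer in network.layers for g in layer.grads]
    params = [p for layer in network.layers for p in layer.params]
    check_rng = np.random.default_rng(99)
    for p, g in zip(params, analytic):
        flat = np.ravel(p)
        for _ in range(min(5, flat.size)):
            idx = np.unravel_index(check_rng.integers(p.size), p.shape)
            num = _numeric_grad(network, x, t, p, idx)
            assert num == pytest.approx(g[idx], abs=atol, rel=rtol), (p.shape, idx)


@pytest.mark.parametrize("head", ["sigmoid", "softmax"])
def test_lstm_network_gradients_match_finite_differences(head):
    rng = np.random.default_rng(1)
    net = nn.Network([nn.LSTM(3, 1, rng), nn.Dense(3, 2, rng)], head=head)
    x = rng.normal(size=(4, 7, 1))
    t = nn.one_hot(np.array([0, 1, 1, 0]))
    _check_grads(net, x, t)


def test_cnn_network_gradients_match_finite_differences():
    rng = np.random.default_rng(2)
    net = nn.Network([
        nn.Conv1D(3, 3, 1, rng), nn.ReLU(), nn.BatchNorm(3),
        nn.Flatten(), nn.Dense(6 * 3, 2, rng),
    ], head="sigmoid")
    x = rng.normal(size=(5, 8, 1))
    t = nn.one_hot(np.array([0, 1, 1, 0, 1]))
    _check_grads(net, x, t, rtol=1e-3)


def test_lstm_jit_kernel_matches_numpy_reference(monkeypatch):
    """The compiled recurrence kernel reproduces the numpy path's loss and
    gradients to floating-point noise."""
    if nn._lk is None:
        pytest.skip("numba kernels unavailable")
    rng = np.random.default_rng(8)
    x = rng.normal(size=(6, 12, 1))
    t = nn.one_hot(rng.integers(0, 2, 6))

    def run():
        r = np.random.default_rng(55)
        net = nn.Network([nn.LSTM(4, 1, r), nn.Dense(4, 2, r)])
        loss, _ = net.train_step(x, t, _NullAdam(), np.random.default_rng(0))
        return loss, [g.copy() for layer in net.layers for g in layer.grads]

    loss_jit, grads_jit = run()
    monkeypatch.setattr(nn, "_lk", None)
    loss_ref, grads_ref = run()
    assert loss_jit == pytest.approx(loss_ref, abs=1e-12)
    for a, b in zip(grads_jit, grads_ref):
        np.testing.assert_allclose(a, b, atol=1e-12)


def test_batchnorm_jit_kernel_matches_numpy_reference(monkeypatch):
    if nn._lk is None:
        pytest.skip("numba kernels unavailable")
    rng = np.random.default_rng(9)
    x = rng.normal(loc=2.0, scale=3.0, size=(8, 7, 5))
    g = rng.normal(size=(8, 7, 5))
    bn_jit, bn_ref = nn.BatchNorm(5), nn.BatchNorm(5)
    y_jit = bn_jit.forward(x, True, None)
    dx_jit = bn_jit.backward(g)
    monkeypatch.setattr(nn, "_lk", None)
    y_ref = bn_ref.forward(x, True, None)
    dx_ref = bn_ref.backward(g)
    np.testing.assert_allclose(y_jit, y_ref, atol=1e-12)
    np.testing.assert_allclose(dx_jit, dx_ref, atol=1e-12)
    np.testing.assert_allclose(bn_jit.grads[0], bn_ref.grads[0], atol=1e-12)
    np.testing.assert_allclose(bn_jit.running_var, bn_ref.running_var, atol=1e-12)


def test_lstm_parameter_count_closed_form():
    """4·(u·(f+u)+u) kernel/recurrent/bias plus (u·2+2) dense = 106 for u=4, f=1."""
    cfg = ClassifierConfig(arch="lstm", segment_length=50, lstm_units=4)
    net = build_lstm(cfg)
    u, f = 4, 1
    assert net.n_params == 4 * (u * (f + u) + u) + (u * 2 + 2) == 106


def test_conv_output_length_valid_padding():
    """Kernel 3 without padding shortens a length-50 input to 48 per filter."""
    cfg = ClassifierConfig(arch="cnn", segment_length=50)
    rng = np.random.default_rng(0)
    conv = nn.Conv1D(cfg.conv_filters, cfg.conv_kernel, 1, rng)
    y = conv.forward(rng.normal(size=(2, 50, 1)), False, None)
    assert y.shape == (2, 48, 32)


@pytest.mark.parametrize("arch,Y", [("lstm", 50), ("cnn", 50), ("cnn", 100),
                                    ("cnn_deep", 200), ("lstm", 200)])
def test_output_shape_and_score_range(arch, Y):
    cfg = ClassifierConfig(arch=arch, segment_length=Y,
                           conv_blocks=3 if arch == "cnn_deep" else 1)
    net = build_lstm(cfg) if arch == "lstm" else build_cnn(cfg)
    x = np.random.default_rng(3).normal(size=(6, Y, 1))
    scores = net.predict_scores(x)
    assert scores.shape == (6, 2)
    assert np.all((scores >= 0) & (scores <= 1))


def test_untrained_accuracy_near_chance_on_balanced_data():
    rng = np.random.default_rng(4)
    cfg = ClassifierConfig(arch="cnn", segment_length=50, train_seed=5)
    net = build_cnn(cfg)
    x = rng.normal(size=(400, 50, 1))
    y = np.repeat([0, 1], 200)
    acc = np.mean(net.predict(x) == y)
    assert 0.4 <= acc <= 0.6


def test_dropout_scales_and_masks_only_in_training():
    d = nn.Dropout(0.5)
    x = np.ones((1000, 4))
    out_eval = d.forward(x, False, None)
    np.testing.assert_array_equal(out_eval, x)
    out_train = d.forward(x, True, np.random.default_rng(0))
    kept = out_train > 0
    assert 0.4 < kept.mean() < 0.6
    np.testing.assert_allclose(out_train[kept], 2.0)


def test_batchnorm_normalizes_training_batches():
    bn = nn.BatchNorm(3)
    x = np.random.default_rng(0).normal(loc=5.0, scale=3.0, size=(64, 10, 3))
    y = bn.forward(x, True, None)
    np.testing.assert_allclose(y.mean(axis=(0, 1)), 0.0, atol=1e-10)
    np.testing.assert_allclose(y.std(axis=(0, 1)), 1.0, atol=0.01)


def test_adam_minimizes_a_quadratic():
    class Quad(nn.Layer):
        def __init__(self):
            super().__init__()
            self.w = np.array([5.0, -3.0])
            self.params = [self.w]
            self.grads = [np.zeros(2)]

    layer = Quad()
    opt = nn.Adam(lr=0.05)
    for _ in range(600):
        layer.grads[0][...] = 2 * layer.w
        opt.step([layer])
    assert np.all(np.abs(layer.w) < 1e-3)


def test_weight_save_restore_round_trip():
    rng = np.random.default_rng(6)
    cfg = ClassifierConfig(arch="lstm", segment_length=20)
    net = build_lstm(cfg)
    w = net.get_weights()
    x = rng.normal(size=(8, 20, 1))
    before = net.predict_scores(x)
    net.train_step(x, nn.one_hot(np.zeros(8, dtype=int)), nn.Adam(0.1),
                   np.random.default_rng(0))
    net.set_weights(w)
    np.testing.assert_array_equal(net.predict_scores(x), before)
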