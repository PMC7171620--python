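"""Tests of the scalar-generic neural-network engine."""

import numpy as np
import pytest

from morenet import crypto, engine, nn
from morenet.engine import Tensor, from_plain


@pytest.fixture(scope="module")
def small_cnn():
    return nn.ModelSpec(
        (1, 8, 8),
        [nn.Conv2D(2), nn.Activation("sigmoid"), nn.AvgPool(), nn.Flatten(),
         nn.Dense(5), nn.Activation("tanh"), nn.Dropout(0.25),
         nn.Dense(3), nn.Activation("softmax")],
    )


class TestPresetArchitectures:
    def test_digit_cnn_shapes(self):
        spec = nn.cnn_mnist()
        shapes = spec.output_shapes()
        assert shapes[0] == (8, 28, 28)
        assert shapes[2] == (8, 14, 14)
        assert shapes[3] == (16, 14, 14)
        assert shapes[5] == (16, 7, 7)
        assert shapes[6] == (784,)
        assert shapes[7] == (100,)
        assert shapes[9] == (10,)

    def test_angio_cnn_shapes(self):
        spec = nn.cnn_angio()
        shapes = spec.output_shapes()
        assert spec.input_shape == (1, 256, 256)
        assert shapes[0] == (4, 256, 256)
        assert shapes[2] == (4, 128, 128)
        assert shapes[11] == (32, 16, 16)
        assert shapes[12] == (8192,)
        assert shapes[13] == (64,)
        assert shapes[-1] == (1,)

    def test_wbc_fcnn_shapes(self):
        spec = nn.fcnn_wbc()
        shapes = [s for s in spec.output_shapes()]
        assert spec.input_shape == (9,)
        assert shapes[0] == shapes[2] == shapes[4] == (40,)
        assert shapes[-1] == (12,)


class TestXavierInit:
    def test_dense_bound(self):
        spec = nn.ModelSpec((9,), [nn.Dense(40)])
        params = nn.xavier_init(spec, 0)
        L = np.sqrt(6.0 / 49.0)
        W = params.layers[0]["W"].values
        assert L == pytest.approx(0.349927, abs=1e-6)
        assert np.all(np.abs(W) <= L)
        # a uniform draw over [-L, L] should fill most of the interval
        assert W.max() > 0.8 * L and W.min() < -0.8 * L

    def test_conv_fans_count_kernel_taps(self):
        spec = nn.ModelSpec((3, 8, 8), [nn.Conv2D(4)])
        W = nn.xavier_init(spec, 1).layers[0]["W"].values
        L = np.sqrt(6.0 / (9 * 3 + 9 * 4))
        assert np.all(np.abs(W) <= L) and W.max() > 0.8 * L

    def test_deterministic_and_zero_biases(self, small_cnn):
        p1 = nn.xavier_init(small_cnn, 7)
        p2 = nn.xavier_init(small_cnn, 7)
        for a, b in zip(p1.layers, p2.layers):
            if a is None:
                continue
            assert np.array_equal(a["W"].values, b["W"].values)
            assert np.all(a["b"].values == 0.0)


class TestParameterEncryption:
    def test_round_trip(self, small_cnn, key, config):
        p = nn.xavier_init(small_cnn, 3)
        enc = nn.encrypt_parameters(p, key, config)
        dec = nn.decrypt_parameters(enc, key)
        for a, b in zip(p.layers, dec.layers):
            if a is None:
                continue
            assert np.allclose(a["W"].values, b["W"].values, rtol=1e-12, atol=1e-12)
            assert np.allclose(b["b"].values, 0.0, atol=1e-12)

    def test_nondeterministic_ciphertexts(self, small_cnn, key, config):
        p = nn.xavier_init(small_cnn, 3)
        e1 = nn.encrypt_parameters(p, key, config)
        e2 = nn.encrypt_parameters(p, key, config)
        assert not np.allclose(e1.layers[0]["W"].values, e2.layers[0]["W"].values)


def _finite_difference_check(spec, loss, x, y, seed=0, eps=1e-6, tol=1e-5):
    params = nn.xavier_init(spec, seed)
    rng = np.random.default_rng(5)

    def loss_of():
        dr = np.random.default_rng(11)
        yp, _ = nn.forward(spec, params, x, train_mode=True, dropout_rng=dr)
        lt, _, _ = nn.loss_and_output_grad(loss, yp, y)
        return float(lt.values)

    dr = np.random.default_rng(11)
    yp, caches = nn.forward(spec, params, x, train_mode=True, dropout_rng=dr)
    lt, g, skip = nn.loss_and_output_grad(loss, yp, y)
    grads = nn.backward(spec, params, caches, g, skip)
    worst = 0.0
    for li, entry in enumerate(params.layers):
        if entry is None:
            continue
        for k, t in entry.items():
            flat = t.values.ravel()
            for i in rng.choice(flat.size, size=min(8, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss_of()
                flat[i] = old - eps
                lm = loss_of()
                flat[i] = old
                fd = (lp - lm) / (2 * eps)
                an = grads[li][k].values.ravel()[i]
                worst = max(worst, abs(fd - an) / max(1e-6, abs(fd) + abs(an)))
    assert worst < tol, worst


class TestGradients:
    def test_cnn_softmax_ce(self, small_cnn, rng):
        x = from_plain(rng.random((4, 1, 8, 8)))
        y = np.zeros((4, 3))
        y[np.arange(4), rng.integers(0, 3, 4)] = 1.0
        _finite_difference_check(small_cnn, "ce", x, y)

    def test_dense_tanh_sigmoid_mse(self, rng):
        spec = nn.fcnn_wbc(n_inputs=5, hidden=7, n_outputs=4)
        x = from_plain(rng.standard_normal((6, 5)))
        y = from_plain(rng.standard_normal((6, 4)))
        _finite_difference_check(spec, "mse", x, y)

    def test_binary_sigmoid_bce(self, rng):
        spec = nn.ModelSpec((1, 4, 4), [
            nn.Conv2D(2), nn.Activation("tanh"), nn.AvgPool(), nn.Flatten(),
            nn.Dense(1), nn.Activation("sigmoid")])
        x = from_plain(rng.random((5, 1, 4, 4)))
        y = rng.integers(0, 2, (5, 1)).astype(float)
        _finite_difference_check(spec, "bce", x, y)

    def test_zero_output_grad_gives_zero_param_grads(self, small_cnn, rng):
        params = nn.xavier_init(small_cnn, 0)
        x = from_plain(rng.random((3, 1, 8, 8)))
        yp, caches = nn.forward(spec := small_cnn, params, x)
        zero = engine.zeros(yp.shape, yp.kind)
        grads = nn.backward(spec, params, caches, zero, skip_last_activation=True)
        for g in grads:
            if g is None:
                continue
            assert np.all(g["W"].values == 0.0) and np.all(g["b"].values == 0.0)


class TestLosses:
    def test_perfect_prediction_zero_ce(self):
        y = np.zeros((3, 4))
        y[np.arange(3), [0, 2, 3]] = 1.0
        lt, _, _ = nn.loss_and_output_grad("ce", from_plain(y.copy()), y)
        assert float(lt.values) == pytest.approx(0.0, abs=1e-12)

    def test_softmax_sums_to_one_both_kinds(self, key, config, rng):
        z = rng.standard_normal((8, 10))
        plain = nn._softmax(from_plain(z))
        assert np.allclose(plain.values.sum(axis=1), 1.0, atol=1e-9)
        cz = engine.encrypt_tensor(from_plain(z), key, config)
        cipher = nn._softmax(cz)
        dec = crypto.decrypt_array(cipher.values, key)
        assert np.allclose(dec.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(dec, plain.values, atol=1e-9)


class TestOptimizer:
    def test_plain_gradient_step(self):
        spec = nn.ModelSpec((2,), [nn.Dense(2)])
        p = nn.xavier_init(spec, 0)
        w0 = p.layers[0]["W"].values.copy()
        grads = [{"W": from_plain(w0.copy()), "b": from_plain(np.zeros(2))}]
        nn.sgd_momentum_step(p, grads, lr=1.0, mu=0.0)
        assert np.allclose(p.layers[0]["W"].values, 0.0)

    def test_zero_gradient_fixed_point(self):
        spec = nn.ModelSpec((2,), [nn.Dense(2)])
        p = nn.xavier_init(spec, 0)
        w0 = p.layers[0]["W"].values.copy()
        grads = [{"W": from_plain(np.zeros((2, 2))), "b": from_plain(np.zeros(2))}]
        nn.sgd_momentum_step(p, grads, lr=0.1, mu=0.9)
        assert np.array_equal(p.layers[0]["W"].values, w0)

    def test_momentum_recurrence(self):
        # scalar recurrence: v1 = -lr*g1, w1 = w0+v1; v2 = mu*v1 - lr*g2, w2 = w1+v2
        spec = nn.ModelSpec((1,), [nn.Dense(1)])
        p = nn.xavier_init(spec, 0)
        w0 = float(p.layers[0]["W"].values[0, 0])
        lr, mu, g1, g2 = 0.1, 0.9, 0.5, -0.2
        nn.sgd_momentum_step(p, [{"W": from_plain(np.array([[g1]])),
                                  "b": from_plain(np.zeros(1))}], lr, mu)
        nn.sgd_momentum_step(p, [{"W": from_plain(np.array([[g2]])),
                                  "b": from_plain(np.zeros(1))}], lr, mu)
        v1 = -lr * g1
        v2 = mu * v1 - lr * g2
        assert float(p.layers[0]["W"].values[0, 0]) == pytest.approx(w0 + v1 + v2, rel=1e-12)


class TestEncryptedEquivalence:
    def test_forward_and_backward_match_plaintext(self, small_cnn, key, rng):
        # log-bearing pipelines (CE loss monitoring) need fillers commensurate
        # with the messages, else the filler track of softmax probabilities
        # underflows past the eigenvalue-recovery floor
        config = crypto.EncryptionConfig(rng_seed=77, r_low=0.2, r_high=2.0)
        params = nn.xavier_init(small_cnn, 2)
        x = rng.random((3, 1, 8, 8))
        y = np.zeros((3, 3))
        y[np.arange(3), [0, 1, 2]] = 1.0
        dr1 = np.random.default_rng(21)
        yp_p, caches_p = nn.forward(small_cnn, params, from_plain(x), True, dr1)
        lt_p, g_p, skip = nn.loss_and_output_grad("ce", yp_p, y)
        grads_p = nn.backward(small_cnn, params, caches_p, g_p, skip)

        cparams = nn.encrypt_parameters(params, key, config)
        cx = engine.encrypt_tensor(from_plain(x), key, config)
        dr2 = np.random.default_rng(21)
        yp_c, caches_c = nn.forward(small_cnn, cparams, cx, True, dr2)
        lt_c, g_c, skip_c = nn.loss_and_output_grad("ce", yp_c, y)
        grads_c = nn.backward(small_cnn, cparams, caches_c, g_c, skip_c)

        assert np.allclose(crypto.decrypt_array(yp_c.values, key), yp_p.values, atol=1e-8)
        assert float(crypto.decrypt_array(lt_c.values[None], key)[0]) == pytest.approx(
            float(lt_p.values), rel=1e-6, abs=1e-9)
        for gp, gc in zip(grads_p, grads_c):
            if gp is None:
                continue
            for k in gp:
                dec = crypto.decrypt_array(gc[k].values, key)
                assert np.allclose(dec, gp[k].values, atol=1e-7)

    def test_training_runs_identically(self, key, config, rng):
        spec = nn.fcnn_wbc(n_inputs=4, hidden=8, n_outputs=3)
        X = rng.random((48, 4))
        Y = rng.random((48, 3))
        tc = nn.TrainConfig(loss="mse", epochs=4, batch_size=16, shuffle_seed=3, dropout_seed=4)
        p0 = nn.xavier_init(spec, 9)
        pp, lp = nn.train(spec, from_plain(X), from_plain(Y), tc, params=p0.copy())
        pc, lc = nn.train(
            spec,
            engine.encrypt_tensor(from_plain(X), key, config),
            engine.encrypt_tensor(from_plain(Y), key, config),
            tc, params=nn.encrypt_parameters(p0, key, config), monitor_key=key)
        dec = nn.decrypt_parameters(pc, key)
        for a, b in zip(pp.layers, dec.layers):
            if a is None:
                continue
            assert np.allclose(a["W"].values, b["W"].values, rtol=1e-6, atol=1e-9)
        assert np.allclose(lp, lc, rtol=1e-6, atol=1e-9)

    def test_convergence_on_linear_toy(self, rng):
        # loss after 20 epochs clearly below the first epoch on a learnable map
        spec = nn.fcnn_wbc(n_inputs=3, hidden=10, n_outputs=2)
        X = rng.standard_normal((200, 3))
        W = rng.standard_normal((3, 2))
        Y = np.tanh(X @ W)
        tc = nn.TrainConfig(loss="mse", epochs=20, batch_size=32, shuffle_seed=0)
        _, losses = nn.train(spec, from_plain(X), from_plain(Y), tc)
        assert losses[19] < losses[0]


class TestPredict:
    def test_dropout_inert_at_inference(self, small_cnn, rng):
        params = nn.xavier_init(small_cnn, 1)
        x = from_plain(rng.random((4, 1, 8, 8)))
        y1 = nn.predict(small_cnn, params, x)
        y2 = nn.predict(small_cnn, params, x)
        assert np.array_equal(y1.values, y2.values)

    def test_encrypted_inference_matches_plaintext(self, small_cnn, key, rng):
        # message-scale fillers: softmax exponentiates the filler logits, so
        # wide fillers would cost float64 precision on the message track
        config = crypto.EncryptionConfig(rng_seed=55, r_low=-1.0, r_high=1.0)
        params = nn.xavier_init(small_cnn, 4)
        x = rng.random((10, 1, 8, 8))
        yp = nn.predict(small_cnn, params, from_plain(x))
        cy = nn.predict(small_cnn, nn.encrypt_parameters(params, key, config),
                        engine.encrypt_tensor(from_plain(x), key, config))
        assert cy.kind == engine.CIPHER
        dec = crypto.decrypt_array(cy.values, key)
        assert np.allclose(dec, yp.values, atol=1e-8)
        assert np.array_equal(dec.argmax(axis=1), yp.values.argmax(axis=1))

    def test_shape_mismatch_rejected(self, small_cnn, rng):
        params = nn.xavier_init(small_cnn, 0)
        with pytest.raises(ValueError):
            nn.forward(small_cnn, params, from_plain(rng.random((2, 1, 7, 7))))
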