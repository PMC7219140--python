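"""Regression engines: cell equations, stacking, gradients, training."""

import json
import math

import numpy as np
import pytest

from neurogc import neural_models as nm
from neurogc.neural_models import (
    BiLSTMParams,
    GateParams,
    LSTMLayerParams,
    MLPParams,
    MLPRegressor,
    PredictorConfig,
    StackedLSTMRegressor,
    bilstm_predict,
    feedforward_predict,
    lstm_step,
    nn_gc_hidden_size,
    params_from_json,
    params_to_json,
)


def _zero_layer(hidden, inputs):
    g = lambda: GateParams(W=np.zeros((hidden, inputs)), V=np.zeros((hidden, hidden)),
                           b=np.zeros(hidden))
    return LSTMLayerParams(g(), g(), g(), g())


def _scalar_layer(w):
    g = lambda: GateParams(W=np.full((1, 1), w), V=np.zeros((1, 1)), b=np.zeros(1))
    return LSTMLayerParams(g(), g(), g(), g())


class TestLSTMStep:
    def test_zero_parameters_give_half_gates_zero_state(self):
        layer = _zero_layer(3, 2)
        h, c = lstm_step(np.ones(2), np.zeros(3), np.zeros(3), layer)
        np.testing.assert_array_equal(c, np.zeros(3))
        np.testing.assert_array_equal(h, np.zeros(3))

    def test_scalar_hand_computed_case(self):
        # independent scalar oracle: all W=1, V=0, b=0, x=1, states 0
        sig1 = 1.0 / (1.0 + math.exp(-1.0))          # i = f = o = sigma(1)
        c_exp = sig1 * math.tanh(1.0)                # f*0 + i*tanh(1)
        h_exp = sig1 * math.tanh(c_exp)
        h, c = lstm_step(np.ones(1), np.zeros(1), np.zeros(1), _scalar_layer(1.0))
        assert c[0] == pytest.approx(c_exp, abs=1e-10)
        assert h[0] == pytest.approx(h_exp, abs=1e-10)
        assert sig1 == pytest.approx(0.7311, abs=1e-4)
        assert h[0] == pytest.approx(0.3697, abs=1e-4)

    def test_hidden_state_strictly_bounded(self, rng):
        layer = LSTMLayerParams(*[
            GateParams(W=rng.normal(size=(4, 3)) * 5, V=rng.normal(size=(4, 4)) * 5,
                       b=rng.normal(size=4) * 5)
            for _ in range(4)
        ])
        h, _ = lstm_step(rng.normal(size=3) * 10, rng.normal(size=4),
                         rng.normal(size=4) * 10, layer)
        assert np.all(np.abs(h) < 1.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension mismatch"):
            lstm_step(np.ones(3), np.zeros(2), np.zeros(2), _zero_layer(2, 2))


class TestBiLSTMPredict:
    def test_zero_parameters_predict_zero(self):
        # depth-2 stack: second layer consumes 6 concatenated features
        p = BiLSTMParams([_zero_layer(3, 2), _zero_layer(3, 6)],
                         [_zero_layer(3, 2), _zero_layer(3, 6)],
                         readout_weight=np.zeros(6), readout_bias=0.0)
        assert bilstm_predict(np.ones((5, 2)), p) == 0.0

    def test_empty_window_rejected(self):
        p = BiLSTMParams([_zero_layer(2, 2)], [], np.zeros(2), 0.0)
        with pytest.raises(ValueError, match="empty window"):
            bilstm_predict(np.empty((0, 2)), p)

    def test_unequal_depths_rejected(self):
        with pytest.raises(ValueError, match="equal depth"):
            BiLSTMParams([_zero_layer(2, 2)] * 2, [_zero_layer(2, 2)], np.zeros(4), 0.0)

    def test_zeroed_backward_half_reduces_to_unidirectional(self, rng):
        cfg = PredictorConfig(hidden_units=4, depth=1, seed=2)
        model = StackedLSTMRegressor(3, cfg, bidirectional=True)
        p = model.to_params()
        # silence the backward stack and its readout half
        zb = _zero_layer(4, 3)
        p_cut = BiLSTMParams(p.forward_layers, [zb],
                             readout_weight=np.concatenate([p.readout_weight[:4],
                                                            np.zeros(4)]),
                             readout_bias=p.readout_bias,
                             pos_forward=p.pos_forward, pos_backward=p.pos_backward)
        p_uni = BiLSTMParams(p.forward_layers, [], p.readout_weight[:4],
                             p.readout_bias, pos_forward=p.pos_forward)
        w = rng.normal(size=(6, 3))
        assert bilstm_predict(w, p_cut) == pytest.approx(bilstm_predict(w, p_uni), abs=1e-12)

    def test_single_timestep_matches_independent_composition(self, rng):
        """Depth-1 prediction on a length-1 window, rebuilt from raw formulas."""
        cfg = PredictorConfig(hidden_units=3, depth=1, seed=4)
        model = StackedLSTMRegressor(2, cfg, bidirectional=True)
        p = model.to_params()
        x = rng.normal(size=2)

        def cell(layer, x):
            sig = lambda v: 1.0 / (1.0 + np.exp(-v))
            i = sig(layer.input_gate.W @ x + layer.input_gate.b)
            f = sig(layer.forget_gate.W @ x + layer.forget_gate.b)
            o = sig(layer.output_gate.W @ x + layer.output_gate.b)
            c = i * np.tanh(layer.cell.W @ x + layer.cell.b)
            return o * np.tanh(c)

        hf = cell(p.forward_layers[0], x)
        hb = cell(p.backward_layers[0], x)
        expected = np.concatenate([hf, hb]) @ p.readout_weight + p.readout_bias
        assert bilstm_predict(x[None, :], p) == pytest.approx(expected, abs=1e-12)

    def test_fused_and_functional_paths_agree(self, rng):
        cfg = PredictorConfig(hidden_units=5, depth=3, seed=0)
        model = StackedLSTMRegressor(4, cfg, bidirectional=True,
                                     pos_forward=3, pos_backward=4)
        X = rng.normal(size=(7, 8, 4))
        p = model.to_params()
        batch = model.predict(X)
        singles = np.array([bilstm_predict(X[i], p) for i in range(7)])
        np.testing.assert_allclose(batch, singles, atol=1e-12)

    def test_numba_and_numpy_paths_agree(self, rng, monkeypatch):
        if not nm._HAVE_KERNELS:
            pytest.skip("compiled kernels unavailable")
        cfg = PredictorConfig(hidden_units=4, depth=2, seed=1)
        model = StackedLSTMRegressor(3, cfg, bidirectional=True,
                                     pos_forward=2, pos_backward=3)
        X = rng.normal(size=(10, 6, 3))
        y = rng.normal(size=10)
        yh_fast, ctx_fast = model._forward(X, need_cache=True)
        g_fast, dw_fast, db_fast = model._backward(2 * (yh_fast - y) / 10, ctx_fast)
        monkeypatch.setattr(nm, "_HAVE_KERNELS", False)
        yh_ref, ctx_ref = model._forward(X, need_cache=True)
        g_ref, dw_ref, db_ref = model._backward(2 * (yh_ref - y) / 10, ctx_ref)
        np.testing.assert_allclose(yh_fast, yh_ref, atol=1e-12)
        for a, b in zip(g_fast + [dw_fast, db_fast], g_ref + [dw_ref, db_ref]):
            np.testing.assert_allclose(a, b, atol=1e-11)


class TestGradients:
    @pytest.mark.parametrize("bidirectional", [True, False])
    def test_bptt_matches_finite_differences(self, rng, bidirectional):
        cfg = PredictorConfig(hidden_units=4, depth=2 if bidirectional else 1, seed=0)
        m = StackedLSTMRegressor(3, cfg, bidirectional=bidirectional,
                                 pos_forward=4, pos_backward=5)
        X = rng.normal(size=(6, 10, 3))
        y = rng.normal(size=6)
        yhat, ctx = m._forward(X, need_cache=True)
        grads, dw, db = m._backward(2 * (yhat - y) / 6, ctx)
        arrays = m._param_arrays() + [m.w_out, m.b_out]
        analytic = grads + [dw, db]

        def loss():
            yh, _ = m._forward(X, need_cache=False)
            return float(np.mean((yh - y) ** 2))

        eps = 1e-5
        for arr, g in zip(arrays, analytic):
            flat = arr.ravel()
            for k in rng.choice(arr.size, size=min(arr.size, 3), replace=False):
                old = flat[k]
                flat[k] = old + eps
                up = loss()
                flat[k] = old - eps
                dn = loss()
                flat[k] = old
                num = (up - dn) / (2 * eps)
                assert g.ravel()[k] == pytest.approx(num, rel=1e-3, abs=1e-7)

    def test_mlp_gradients(self, rng):
        cfg = PredictorConfig(seed=0, epochs=1)
        net = MLPRegressor(6, cfg)
        X = rng.normal(size=(8, 6))
        y = rng.normal(size=8)
        yhat, (Xc, A, Hh) = net._forward(X)
        dyhat = 2 * (yhat - y) / 8
        dw2 = Hh.T @ dyhat
        dA = np.outer(dyhat, net.w2) * (1 - Hh * Hh)
        dW1 = dA.T @ Xc

        def loss():
            return float(np.mean((net.predict(X) - y) ** 2))

        eps = 1e-6
        for arr, g in ((net.W1, dW1), (net.w2, dw2)):
            flat = arr.ravel()
            for k in rng.choice(arr.size, size=3, replace=False):
                old = flat[k]
                flat[k] = old + eps
                up = loss()
                flat[k] = old - eps
                dn = loss()
                flat[k] = old
                assert g.ravel()[k] == pytest.approx((up - dn) / (2 * eps),
                                                     rel=1e-4, abs=1e-8)


class TestFeedForward:
    def test_zero_weights_predict_bias(self):
        p = MLPParams(W1=np.zeros((4, 6)), b1=np.zeros(4), w2=np.zeros(4), b2=1.5)
        assert feedforward_predict(np.ones(6), p) == 1.5

    def test_two_thirds_hidden_rounding(self):
        assert nn_gc_hidden_size(25) == 17   # 5 channels x order 5
        assert nn_gc_hidden_size(49) == 33   # 7 channels x order 7
        assert nn_gc_hidden_size(6) == 4

    def test_dimension_mismatch(self):
        p = MLPParams(W1=np.zeros((4, 6)), b1=np.zeros(4), w2=np.zeros(4), b2=0.0)
        with pytest.raises(ValueError, match="input length"):
            feedforward_predict(np.ones(5), p)

    def test_linear_mode_reproduces_least_squares(self, rng):
        """Identity-like hidden weights + OLS readout == the OLS prediction."""
        X = rng.normal(size=(60, 5))
        beta = rng.normal(size=5)
        y = X @ beta + 0.1 * rng.normal(size=60)
        coef, *_ = np.linalg.lstsq(np.column_stack([X, np.ones(60)]), y, rcond=None)
        p = MLPParams(W1=np.eye(5), b1=np.zeros(5), w2=coef[:5], b2=float(coef[5]),
                      activation="linear")
        preds = np.array([feedforward_predict(x, p) for x in X])
        np.testing.assert_allclose(preds, X @ coef[:5] + coef[5], atol=1e-12)


class TestTraining:
    def test_forward_is_pure_and_deterministic(self, rng):
        cfg = PredictorConfig(hidden_units=6, depth=2, seed=3)
        m = StackedLSTMRegressor(2, cfg)
        X = rng.normal(size=(5, 8, 2))
        np.testing.assert_array_equal(m.predict(X), m.predict(X))

    def test_training_reproducible_with_fixed_seed(self, rng):
        X = rng.normal(size=(80, 6, 2))
        y = rng.normal(size=80)
        cfg = PredictorConfig(hidden_units=4, depth=1, epochs=3, seed=7)
        m1 = StackedLSTMRegressor(2, cfg).fit(X, y)
        m2 = StackedLSTMRegressor(2, cfg).fit(X, y)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_overfit_sanity_on_noiseless_ar2_map(self):
        """A depth-1 bi-LSTM driven to convergence fits the deterministic
        AR(2) update to under 1% of signal variance."""
        from neurogc.simulators import simulate

        x = simulate("A", 240, seed=21).series[0]
        T = 10
        X = np.stack([x[t - T:t, None] for t in range(T, 200 + T)])
        y = 0.952 * x[T - 1 + np.arange(200)] - 0.9025 * x[T - 2 + np.arange(200)]
        X = (X - X.mean()) / X.std()
        scale = y.std()
        yn = (y - y.mean()) / scale
        cfg = PredictorConfig(hidden_units=10, depth=1, epochs=400,
                              learning_rate=1e-2, batch_size=200, seed=0)
        m = StackedLSTMRegressor(1, cfg, bidirectional=True).fit(X, yn)
        mse = float(np.mean((m.predict(X) - yn) ** 2))
        assert mse < 0.01

    def test_params_json_round_trip(self):
        cfg = PredictorConfig(hidden_units=3, depth=2, seed=5)
        m = StackedLSTMRegressor(2, cfg)
        p = m.to_params()
        p2 = params_from_json(params_to_json(p))
        w = np.ones((4, 2))
        assert bilstm_predict(w, p) == pytest.approx(bilstm_predict(w, p2), abs=1e-15)
        doc = json.loads(params_to_json(p))
        assert set(doc["forward_layers"][0]) == {
            "input_gate", "forget_gate", "output_gate", "cell",
        }

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PredictorConfig(hidden_units=0)
        with pytest.raises(ValueError):
            PredictorConfig(learning_rate=-1)
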