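"""Sequence-regression engines for neural Granger causality.

Three predictors share one training loop (mini-batch Adam on squared error,
all gradients derived by hand and checked against finite differences in the
test suite):

* :class:`StackedLSTMRegressor` with ``bidirectional=True`` — the bi-LSTM:
  parallel forward-in-time and backward-in-time LSTM stacks; every hidden
  layer above the first receives the concatenated output sequences of the
  forward and backward layers below, and a linear readout maps the
  final-layer states at the prediction position to one value.
* the same class with ``bidirectional=False`` — the unidirectional LSTM used
  by the RNN-GC baseline (readout on the terminal state).
* :class:`MLPRegressor` — the feed-forward baseline, which consumes a
  flattened lag window (deliberately discarding temporal structure) through
  one hidden layer of ``ceil(2/3 × input size)`` units.

The functional entry points :func:`lstm_step`, :func:`bilstm_predict` and
:func:`feedforward_predict` operate on explicit per-gate parameter records
and are intentionally independent of the fused-weight training path, so the
two routes can be cross-checked.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit as _sigmoid

try:  # compiled fast path for the recurrent loops
    from ._lstm_kernels import (
        lstm_backward_loop,
        lstm_forward_loop,
        lstm_forward_nocache,
    )

    _HAVE_KERNELS = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_KERNELS = False

__all__ = [
    "GateParams",
    "LSTMLayerParams",
    "BiLSTMParams",
    "MLPParams",
    "PredictorConfig",
    "lstm_step",
    "bilstm_predict",
    "feedforward_predict",
    "StackedLSTMRegressor",
    "MLPRegressor",
    "params_to_json",
    "params_from_json",
]


# --------------------------------------------------------------------------
# explicit parameter records
# --------------------------------------------------------------------------

@dataclass
class GateParams:
    """One gate's affine map: ``W x_t + V h_{t-1} + b``."""

    W: np.ndarray  # (hidden, input)
    V: np.ndarray  # (hidden, hidden)
    b: np.ndarray  # (hidden,)

    def __post_init__(self) -> None:
        H = self.b.shape[0]
        if self.W.shape[0] != H or self.V.shape != (H, H):
            raise ValueError(
                f"inconsistent gate shapes W{self.W.shape} V{self.V.shape} b{self.b.shape}"
            )


@dataclass
class LSTMLayerParams:
    """All four gates of one LSTM layer (input, forget, output, cell)."""

    input_gate: GateParams
    forget_gate: GateParams
    output_gate: GateParams
    cell: GateParams

    @property
    def hidden_size(self) -> int:
        return self.input_gate.b.shape[0]

    @property
    def input_size(self) -> int:
        return self.input_gate.W.shape[1]


@dataclass
class BiLSTMParams:
    """A stacked bidirectional LSTM plus its linear readout.

    ``readout_weight`` maps the concatenation of the final layer's forward
    state at window index ``pos_forward`` and backward state at window index
    ``pos_backward`` to a scalar.  When ``backward_layers`` is empty the
    model is unidirectional and the readout consumes the forward state only.
    """

    forward_layers: list[LSTMLayerParams]
    backward_layers: list[LSTMLayerParams]
    readout_weight: np.ndarray
    readout_bias: float
    pos_forward: int = -1
    pos_backward: int = 0

    def __post_init__(self) -> None:
        if self.backward_layers and len(self.backward_layers) != len(self.forward_layers):
            raise ValueError("forward and backward stacks must have equal depth")


@dataclass
class MLPParams:
    """One-hidden-layer perceptron: ``w2 · act(W1 v + b1) + b2``."""

    W1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    activation: str = "tanh"  # "tanh" | "linear"


@dataclass
class PredictorConfig:
    """Training hyperparameters shared by all engines.

    Defaults follow the connectivity protocol: 10 hidden units, context
    windows of at most 20 samples, a three-layer stack for the
    bidirectional model, Adam on mean-squared error.
    """

    hidden_units: int = 10
    max_sequence_length: int = 20
    depth: int = 3
    epochs: int = 50
    learning_rate: float = 1e-2
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hidden_units", "max_sequence_length", "depth", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


# --------------------------------------------------------------------------
# functional forward passes (explicit per-gate parameters)
# --------------------------------------------------------------------------

def lstm_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    params: LSTMLayerParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update.

    Gates ``i, f, o`` are sigmoids of their affine maps, the candidate is a
    tanh, the cell mixes forget/input contributions and the hidden state is
    ``o ⊙ tanh(c)``::

        i_t = σ(Wi x_t + Vi h_{t-1} + bi)
        f_t = σ(Wf x_t + Vf h_{t-1} + bf)
        o_t = σ(Wo x_t + Vo h_{t-1} + bo)
        c_t = f_t ⊙ c_{t-1} + i_t ⊙ tanh(Wc x_t + Vc h_{t-1} + bc)
        h_t = o_t ⊙ tanh(c_t)
    """
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    H = params.hidden_size
    if x_t.shape[-1] != params.input_size or h_prev.shape[-1] != H or c_prev.shape[-1] != H:
        raise ValueError(
            f"dimension mismatch: x{x_t.shape} h{h_prev.shape} c{c_prev.shape} "
            f"vs layer (input={params.input_size}, hidden={H})"
        )
    g = params
    i_t = _sigmoid(x_t @ g.input_gate.W.T + h_prev @ g.input_gate.V.T + g.input_gate.b)
    f_t = _sigmoid(x_t @ g.forget_gate.W.T + h_prev @ g.forget_gate.V.T + g.forget_gate.b)
    o_t = _sigmoid(x_t @ g.output_gate.W.T + h_prev @ g.output_gate.V.T + g.output_gate.b)
    cand = np.tanh(x_t @ g.cell.W.T + h_prev @ g.cell.V.T + g.cell.b)
    c_t = f_t * c_prev + i_t * cand
    h_t = o_t * np.tanh(c_t)
    return h_t, c_t


def _run_layer(seq: np.ndarray, layer: LSTMLayerParams, reverse: bool) -> np.ndarray:
    """Run one layer over a (T, D) sequence; returns (T, H) hidden states."""
    T = seq.shape[0]
    H = layer.hidden_size
    h = np.zeros(H)
    c = np.zeros(H)
    out = np.zeros((T, H))
    order = range(T - 1, -1, -1) if reverse else range(T)
    for t in order:
        h, c = lstm_step(seq[t], h, c, layer)
        out[t] = h
    return out


def bilstm_predict(window: np.ndarray, params: BiLSTMParams) -> float:
    """Pure-function prediction of a stacked (bi)LSTM on one window.

    The forward stack consumes the window left→right, the backward stack
    right→left; each layer above the first receives the concatenated output
    sequences of both directions below it.  The readout is applied to the
    final layer's states at ``pos_forward`` / ``pos_backward``.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if window.shape[0] == 0:
        raise ValueError("empty window")
    seq = window
    hf = hb = None
    for li, fwd in enumerate(params.forward_layers):
        hf = _run_layer(seq, fwd, reverse=False)
        if params.backward_layers:
            hb = _run_layer(seq, params.backward_layers[li], reverse=True)
            seq = np.concatenate([hf, hb], axis=1)
        else:
            seq = hf
    if params.backward_layers:
        state = np.concatenate([hf[params.pos_forward], hb[params.pos_backward]])
    else:
        state = hf[params.pos_forward]
    return float(state @ params.readout_weight + params.readout_bias)


def feedforward_predict(flattened_lags: np.ndarray, params: MLPParams) -> float:
    """One-hidden-layer feed-forward prediction on a flattened lag vector."""
    v = np.asarray(flattened_lags, dtype=float).ravel()
    if v.shape[0] != params.W1.shape[1]:
        raise ValueError(
            f"input length {v.shape[0]} != expected {params.W1.shape[1]}"
        )
    a = params.W1 @ v + params.b1
    hidden = np.tanh(a) if params.activation == "tanh" else a
    return float(params.w2 @ hidden + params.b2)


def nn_gc_hidden_size(n_inputs: int) -> int:
    """Hidden width of the feed-forward baseline: ceil of two thirds of the input width."""
    return math.ceil(2 * n_inputs / 3)


# --------------------------------------------------------------------------
# fused-weight training engine
# --------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-1], shape[0]
    lim = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class _Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place)."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class _FusedLSTMLayer:
    """One direction of one layer, gates fused as rows [i; f; o; g].

    ``reverse=True`` processes sequences right→left (time-reversed), which
    implements the backward stack of the bidirectional model.
    """

    def __init__(self, n_in: int, hidden: int, reverse: bool, rng: np.random.Generator):
        self.H = hidden
        self.reverse = reverse
        self.Wx = _glorot(rng, (4 * hidden, n_in))
        self.Wh = _glorot(rng, (4 * hidden, hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias: remember by default

    @property
    def param_list(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray, need_cache: bool = True):
        """X: (N, T, D) in original time order → H_out: (N, T, H).

        Internally everything is time-major (T, N, ·) so the per-step reads
        and writes of the recurrence are contiguous.
        """
        N, T, _ = X.shape
        H = self.H
        Xp = X[:, ::-1] if self.reverse else X
        Zx = np.ascontiguousarray((Xp @ self.Wx.T + self.b).transpose(1, 0, 2))
        if _HAVE_KERNELS and not need_cache:
            Hs = lstm_forward_nocache(Zx, np.ascontiguousarray(self.Wh.T))
            out = Hs.transpose(1, 0, 2)
            return (out[:, ::-1] if self.reverse else out), None
        if _HAVE_KERNELS:
            Hs, gates, cps, tcs, hps = lstm_forward_loop(
                Zx, np.ascontiguousarray(self.Wh.T)
            )
        else:
            h = np.zeros((N, H))
            c = np.zeros((N, H))
            Hs = np.empty((T, N, H))
            gates = np.empty((T, N, 4 * H))
            cps = np.empty((T, N, H))
            tcs = np.empty((T, N, H))
            hps = np.empty((T, N, H))
            for t in range(T):
                z = Zx[t] + h @ self.Wh.T
                i = _sigmoid(z[:, : 3 * H])  # input/forget/output gates at once
                g = np.tanh(z[:, 3 * H :])
                gates[t, :, : 3 * H] = i
                gates[t, :, 3 * H :] = g
                cps[t] = c
                hps[t] = h
                c = i[:, H : 2 * H] * c + i[:, :H] * g
                tc = np.tanh(c)
                tcs[t] = tc
                h = i[:, 2 * H : 3 * H] * tc
                Hs[t] = h
        cache = ({"X": Xp, "gates": gates, "c": cps, "tc": tcs, "hprev": hps}
                 if need_cache else None)
        out = Hs.transpose(1, 0, 2)
        out = out[:, ::-1] if self.reverse else out
        return out, cache

    def backward(self, dH: np.ndarray, cache: dict):
        """dH: (N, T, H) in original time order → dX, [dWx, dWh, db]."""
        N, T, H = dH.shape
        dHp = dH[:, ::-1] if self.reverse else dH
        dHp = np.ascontiguousarray(dHp.transpose(1, 0, 2))  # (T, N, H)
        Xp = cache["X"]
        gates, cps, tcs = cache["gates"], cache["c"], cache["tc"]
        if _HAVE_KERNELS:
            DZ = lstm_backward_loop(dHp, gates, cps, tcs,
                                    np.ascontiguousarray(self.Wh))
        else:
            DZ = np.empty((T, N, 4 * H))
            dh_next = np.zeros((N, H))
            dc_next = np.zeros((N, H))
            # recurrent part of the reverse sweep; input/weight gradients are
            # accumulated in one batched contraction after the loop
            for t in range(T - 1, -1, -1):
                i, f, o = (gates[t, :, :H], gates[t, :, H : 2 * H],
                           gates[t, :, 2 * H : 3 * H])
                g = gates[t, :, 3 * H :]
                c_prev, tc = cps[t], tcs[t]
                dh = dHp[t] + dh_next
                do = dh * tc
                dc = dc_next + dh * o * (1 - tc * tc)
                dz = DZ[t]
                dz[:, :H] = (dc * g) * i * (1 - i)
                dz[:, H : 2 * H] = (dc * c_prev) * f * (1 - f)
                dz[:, 2 * H : 3 * H] = do * o * (1 - o)
                dz[:, 3 * H :] = (dc * i) * (1 - g * g)
                dc_next = dc * f
                dh_next = dz @ self.Wh
        DZf = DZ.reshape(T * N, 4 * H)
        dWx = DZf.T @ Xp.transpose(1, 0, 2).reshape(T * N, -1)
        dWh = DZf.T @ cache["hprev"].reshape(T * N, H)
        db = DZf.sum(axis=0)
        dXp = (DZ @ self.Wx).transpose(1, 0, 2)
        dX = dXp[:, ::-1] if self.reverse else dXp
        return dX, [dWx, dWh, db]


@dataclass
class _TrainLog:
    loss: list[float] = field(default_factory=list)


class StackedLSTMRegressor:
    """Stacked (bi)directional LSTM with a linear readout, trained by Adam.

    Parameters
    ----------
    n_inputs : int
        Feature dimension per time step (number of channels).
    config : PredictorConfig
    bidirectional : bool
        True → parallel forward/backward stacks of depth ``config.depth``
        whose concatenated sequences feed each level above; False → a single
        forward stack of depth 1 (the RNN-GC engine), regardless of
        ``config.depth``.
    pos_forward, pos_backward : int
        Window indices whose final-layer states feed the readout.  For a
        causal model the defaults (-1, ignored) read the terminal state; for
        a two-sided context window centred on a prediction gap, pass the
        indices flanking the gap.
    """

    def __init__(
        self,
        n_inputs: int,
        config: PredictorConfig,
        bidirectional: bool = True,
        pos_forward: int = -1,
        pos_backward: int = 0,
    ):
        self.config = config
        self.bidirectional = bidirectional
        self.pos_forward = pos_forward
        self.pos_backward = pos_backward
        depth = config.depth if bidirectional else 1
        H = config.hidden_units
        rng = np.random.default_rng(config.seed)
        self.layers: list[dict[str, _FusedLSTMLayer]] = []
        d_in = n_inputs
        for _ in range(depth):
            entry = {"fwd": _FusedLSTMLayer(d_in, H, reverse=False, rng=rng)}
            if bidirectional:
                entry["bwd"] = _FusedLSTMLayer(d_in, H, reverse=True, rng=rng)
                d_in = 2 * H
            else:
                d_in = H
            self.layers.append(entry)
        ro_dim = 2 * H if bidirectional else H
        lim = math.sqrt(6.0 / (ro_dim + 1))
        self.w_out = rng.uniform(-lim, lim, size=ro_dim)
        self.b_out = np.zeros(1)
        self._rng = rng
        self.log = _TrainLog()

    # -- forward / backward ------------------------------------------------

    def _param_arrays(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for entry in self.layers:
            for key in ("fwd", "bwd"):
                if key in entry:
                    out.extend(entry[key].param_list)
        return out

    def _forward(self, X: np.ndarray, need_cache: bool):
        seq = X
        caches = []
        hf = hb = None
        for entry in self.layers:
            hf, cf = entry["fwd"].forward(seq, need_cache)
            if self.bidirectional:
                hb, cb = entry["bwd"].forward(seq, need_cache)
                caches.append((cf, cb))
                seq = np.concatenate([hf, hb], axis=2)
            else:
                caches.append((cf, None))
                seq = hf
        T = X.shape[1]
        pf = self.pos_forward % T
        if self.bidirectional:
            pb = self.pos_backward % T
            state = np.concatenate([hf[:, pf], hb[:, pb]], axis=1)
        else:
            state = hf[:, pf]
        yhat = state @ self.w_out + self.b_out
        return yhat, (caches, hf, hb, state, X.shape)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict targets for windows X of shape (N, T, n_inputs)."""
        yhat, _ = self._forward(np.asarray(X, dtype=float), need_cache=False)
        return yhat

    def _backward(self, dyhat: np.ndarray, ctx) -> list[np.ndarray]:
        caches, hf, hb, state, (N, T, _) = ctx
        H = self.config.hidden_units
        pf = self.pos_forward % T
        dw_out = state.T @ dyhat
        db_out = np.array([dyhat.sum()])
        dstate = np.outer(dyhat, self.w_out)
        dHf = np.zeros_like(hf)
        dHf[:, pf] = dstate[:, :H] if self.bidirectional else dstate
        if self.bidirectional:
            pb = self.pos_backward % T
            dHb = np.zeros_like(hb)
            dHb[:, pb] = dstate[:, H:]
        grads_rev: list[np.ndarray] = []
        for li in range(len(self.layers) - 1, -1, -1):
            entry = self.layers[li]
            cf, cb = caches[li]
            dX_f, gf = entry["fwd"].backward(dHf, cf)
            if self.bidirectional:
                dX_b, gb = entry["bwd"].backward(dHb, cb)
                dSeq = dX_f + dX_b
                grads_rev.extend(reversed(gb))
            else:
                dSeq = dX_f
            grads_rev.extend(reversed(gf))
            if li > 0:
                dHf = dSeq[:, :, :H]
                if self.bidirectional:
                    dHb = dSeq[:, :, H:]
        grads = list(reversed(grads_rev))
        return grads, dw_out, db_out

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "StackedLSTMRegressor":
        """Mini-batch Adam on mean-squared error; seeded, reproducible."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        N = X.shape[0]
        cfg = self.config
        arrays = self._param_arrays() + [self.w_out, self.b_out]
        opt = _Adam(arrays, lr=cfg.learning_rate)
        bs = min(cfg.batch_size, N)
        for _ in range(cfg.epochs):
            order = self._rng.permutation(N)
            ep_loss = 0.0
            for start in range(0, N, bs):
                idx = order[start : start + bs]
                xb, yb = X[idx], y[idx]
                yhat, ctx = self._forward(xb, need_cache=True)
                resid = yhat - yb
                ep_loss += float(resid @ resid)
                dyhat = 2.0 * resid / xb.shape[0]
                grads, dw_out, db_out = self._backward(dyhat, ctx)
                opt.step(grads + [dw_out, db_out])
            self.log.loss.append(ep_loss / N)
        return self

    # -- explicit-parameter view -------------------------------------------

    def to_params(self) -> BiLSTMParams:
        """Export as explicit per-gate parameter records."""
        def split(layer: _FusedLSTMLayer) -> LSTMLayerParams:
            H = layer.H
            gates = []
            for k in range(4):
                sl = slice(k * H, (k + 1) * H)
                gates.append(GateParams(W=layer.Wx[sl].copy(), V=layer.Wh[sl].copy(),
                                        b=layer.b[sl].copy()))
            return LSTMLayerParams(*gates)

        fwd = [split(e["fwd"]) for e in self.layers]
        bwd = [split(e["bwd"]) for e in self.layers] if self.bidirectional else []
        return BiLSTMParams(
            forward_layers=fwd,
            backward_layers=bwd,
            readout_weight=self.w_out.copy(),
            readout_bias=float(np.asarray(self.b_out).ravel()[0]),
            pos_forward=self.pos_forward,
            pos_backward=self.pos_backward,
        )


class MLPRegressor:
    """One-hidden-layer perceptron on flattened lag windows (NN-GC engine).

    Hidden width defaults to ``ceil(2/3 × n_inputs)``.
    """

    def __init__(self, n_inputs: int, config: PredictorConfig,
                 hidden: int | None = None, activation: str = "tanh"):
        self.config = config
        self.activation = activation
        H = hidden if hidden is not None else nn_gc_hidden_size(n_inputs)
        rng = np.random.default_rng(config.seed)
        self.W1 = _glorot(rng, (H, n_inputs))
        self.b1 = np.zeros(H)
        self.w2 = rng.uniform(-math.sqrt(6.0 / (H + 1)), math.sqrt(6.0 / (H + 1)), size=H)
        self.b2 = 0.0
        self._rng = rng
        self.log = _TrainLog()

    def _forward(self, X: np.ndarray):
        A = X @ self.W1.T + self.b1
        Hh = np.tanh(A) if self.activation == "tanh" else A
        yhat = Hh @ self.w2 + self.b2
        return yhat, (X, A, Hh)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float))[0]

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        N = X.shape[0]
        cfg = self.config
        opt = _Adam([self.W1, self.b1, self.w2], lr=cfg.learning_rate)
        bs = min(cfg.batch_size, N)
        for _ in range(cfg.epochs):
            order = self._rng.permutation(N)
            ep_loss = 0.0
            for start in range(0, N, bs):
                idx = order[start : start + bs]
                xb, yb = X[idx], y[idx]
                yhat, (Xc, A, Hh) = self._forward(xb)
                resid = yhat - yb
                ep_loss += float(resid @ resid)
                dyhat = 2.0 * resid / xb.shape[0]
                dw2 = Hh.T @ dyhat
                db2 = dyhat.sum()
                dH = np.outer(dyhat, self.w2)
                dA = dH * (1 - Hh * Hh) if self.activation == "tanh" else dH
                dW1 = dA.T @ Xc
                db1 = dA.sum(axis=0)
                opt.step([dW1, db1, dw2])
                self.b2 -= cfg.learning_rate * db2
            self.log.loss.append(ep_loss / N)
        return self

    def to_params(self) -> MLPParams:
        return MLPParams(W1=self.W1.copy(), b1=self.b1.copy(), w2=self.w2.copy(),
                         b2=float(self.b2), activation=self.activation)


# --------------------------------------------------------------------------
# JSON serialization of explicit parameters (fixture format)
# --------------------------------------------------------------------------

def _gate_to_dict(g: GateParams) -> dict:
    return {"W": g.W.tolist(), "V": g.V.tolist(), "b": g.b.tolist()}


def _gate_from_dict(d: dict) -> GateParams:
    return GateParams(W=np.asarray(d["W"], float), V=np.asarray(d["V"], float),
                      b=np.asarray(d["b"], float))


def _layer_to_dict(lp: LSTMLayerParams) -> dict:
    return {
        "input_gate": _gate_to_dict(lp.input_gate),
        "forget_gate": _gate_to_dict(lp.forget_gate),
        "output_gate": _gate_to_dict(lp.output_gate),
        "cell": _gate_to_dict(lp.cell),
    }


def _layer_from_dict(d: dict) -> LSTMLayerParams:
    return LSTMLayerParams(
        input_gate=_gate_from_dict(d["input_gate"]),
        forget_gate=_gate_from_dict(d["forget_gate"]),
        output_gate=_gate_from_dict(d["output_gate"]),
        cell=_gate_from_dict(d["cell"]),
    )


def params_to_json(params: BiLSTMParams) -> str:
    """Serialize explicit bi-LSTM parameters to a JSON document."""
    doc = {
        "forward_layers": [_layer_to_dict(l) for l in params.forward_layers],
        "backward_layers": [_layer_to_dict(l) for l in params.backward_layers],
        "readout_weight": params.readout_weight.tolist(),
        "readout_bias": params.readout_bias,
        "pos_forward": params.pos_forward,
        "pos_backward": params.pos_backward,
    }
    return json.dumps(doc)


def params_from_json(text: str) -> BiLSTMParams:
    doc = json.loads(text)
    return BiLSTMParams(
        forward_layers=[_layer_from_dict(d) for d in doc["forward_layers"]],
        backward_layers=[_layer_from_dict(d) for d in doc["backward_layers"]],
        readout_weight=np.asarray(doc["readout_weight"], float),
        readout_bias=float(doc["readout_bias"]),
        pos_forward=int(doc["pos_forward"]),
        pos_backward=int(doc["pos_backward"]),
    )
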