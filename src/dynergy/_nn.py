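"""Minimal numpy sequence-classification network.

Implements exactly the stack this package needs: a bidirectional LSTM over
the window sequence (forward/backward outputs concatenated per step),
inverted dropout, a second LSTM returning its last hidden state, a ReLU
dense layer, and a softmax output, trained with RMSprop on categorical
cross-entropy.  Gradients are hand-derived BPTT and are verified against
numerical differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class LSTM:
    """Single-direction LSTM layer (batch, time, features) -> hidden states."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        self.input_size = input_size
        self.hidden_size = hidden_size
        k = np.sqrt(1.0 / hidden_size)
        self.Wx = rng.uniform(-k, k, size=(input_size, 4 * hidden_size))
        self.Wh = rng.uniform(-k, k, size=(hidden_size, 4 * hidden_size))
        self.b = np.zeros(4 * hidden_size)
        self.b[hidden_size: 2 * hidden_size] = 1.0  # forget-gate bias

    @property
    def params(self):
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def forward(self, x: np.ndarray):
        B, T, D = x.shape
        H = self.hidden_size
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        cache = []
        for t in range(T):
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((x[:, t], h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            hs[:, t] = h
        self._cache = cache
        return hs

    def backward(self, dhs: np.ndarray):
        """BPTT given gradients w.r.t. every hidden state; returns dx, grads."""
        cache = self._cache
        B, T, H = dhs.shape
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.empty((B, T, self.input_size))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = cache[t]
            dh = dhs[:, t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g ** 2),
                do * o * (1.0 - o),
            ], axis=1)
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dx, {"Wx": dWx, "Wh": dWh, "b": db}


class BiLSTM:
    """Forward and backward LSTMs with per-step concatenated outputs."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        self.fwd = LSTM(input_size, hidden_size, rng)
        self.bwd = LSTM(input_size, hidden_size, rng)
        self.hidden_size = hidden_size

    @property
    def params(self):
        out = {f"fwd.{k}": v for k, v in self.fwd.params.items()}
        out.update({f"bwd.{k}": v for k, v in self.bwd.params.items()})
        return out

    def forward(self, x: np.ndarray):
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dout: np.ndarray):
        H = self.hidden_size
        dxf, gf = self.fwd.backward(dout[:, :, :H])
        dxb, gb = self.bwd.backward(dout[:, ::-1, H:])
        dx = dxf + dxb[:, ::-1]
        grads = {f"fwd.{k}": v for k, v in gf.items()}
        grads.update({f"bwd.{k}": v for k, v in gb.items()})
        return dx, grads


class Dense:
    def __init__(self, input_size: int, output_size: int, rng: np.random.Generator,
                 relu: bool = False):
        k = np.sqrt(6.0 / (input_size + output_size))
        self.W = rng.uniform(-k, k, size=(input_size, output_size))
        self.b = np.zeros(output_size)
        self.relu = relu

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray):
        z = x @ self.W + self.b
        if self.relu:
            self._mask = z > 0
            z = np.where(self._mask, z, 0.0)
        self._x = x
        return z

    def backward(self, dout: np.ndarray):
        if self.relu:
            dout = dout * self._mask
        grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.W.T, grads


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(shifted)
    return ez / ez.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.log(probs[np.arange(len(y)), y] + eps).mean())


class RMSProp:
    """Keras-style RMSprop: cache = rho cache + (1-rho) g^2."""

    def __init__(self, lr: float = 0.001, rho: float = 0.9, eps: float = 1e-7):
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.cache: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        for name, p in params.items():
            g = grads[name]
            c = self.cache.setdefault(name, np.zeros_like(p))
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)


class SequenceClassifier:
    """BiLSTM -> dropout -> LSTM (last state) -> dense ReLU -> softmax."""

    def __init__(self, input_size: int, n_classes: int,
                 bilstm_units: int = 128, dropout: float = 0.3,
                 lstm_units: int = 64, dense_units: int = 128,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.bilstm = BiLSTM(input_size, bilstm_units, rng)
        self.dropout = dropout
        self.lstm = LSTM(2 * bilstm_units, lstm_units, rng)
        self.dense1 = Dense(lstm_units, dense_units, rng, relu=True)
        self.dense2 = Dense(dense_units, n_classes, rng)
        self.n_classes = n_classes
        self._layers = {
            "bilstm": self.bilstm, "lstm": self.lstm,
            "dense1": self.dense1, "dense2": self.dense2,
        }

    @property
    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for lname, layer in self._layers.items():
            out.update({f"{lname}.{k}": v for k, v in layer.params.items()})
        return out

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        h = self.bilstm.forward(x)
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            self._drop_mask = (rng.random(h.shape) < keep) / keep
            h = h * self._drop_mask
        else:
            self._drop_mask = None
        hs = self.lstm.forward(h)
        last = hs[:, -1]
        self._T = x.shape[1]
        self._lstm_H = hs.shape[2]
        d1 = self.dense1.forward(last)
        return self.dense2.forward(d1)

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        dd1, g2 = self.dense2.backward(dlogits)
        grads.update({f"dense2.{k}": v for k, v in g2.items()})
        dlast, g1 = self.dense1.backward(dd1)
        grads.update({f"dense1.{k}": v for k, v in g1.items()})
        dhs = np.zeros((dlast.shape[0], self._T, self._lstm_H))
        dhs[:, -1] = dlast
        dh, gl = self.lstm.backward(dhs)
        grads.update({f"lstm.{k}": v for k, v in gl.items()})
        if self._drop_mask is not None:
            dh = dh * self._drop_mask
        _, gb = self.bilstm.backward(dh)
        grads.update({f"bilstm.{k}": v for k, v in gb.items()})
        return grads

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray, train: bool = True,
                       rng: np.random.Generator | None = None):
        logits = self.forward(x, train=train, rng=rng)
        probs = softmax(logits)
        loss = cross_entropy(probs, y)
        dlogits = probs.copy()
        dlogits[np.arange(len(y)), y] -= 1.0
        dlogits /= len(y)
        return loss, self.backward(dlogits)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)
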