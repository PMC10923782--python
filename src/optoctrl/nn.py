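"""Minimal NumPy neural-network layer library used by the forecaster.

Implements exactly what the encoder-decoder model needs: LSTM layers with
full backpropagation through time, dense (fully connected) layers, and the
Adam optimizer.  Everything is deterministic given the seed of the
`numpy.random.Generator` used for initialization and batching; there is no
hidden global state.

Shapes follow the batch-first convention: sequences are (B, T, D) and
dense activations (B, D).
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTM", "Dense", "Adam", "relu", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, x)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape, dtype=np.float64) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape).astype(dtype)


class Dense:
    """Fully connected layer with 'relu' or 'linear' activation."""

    def __init__(self, input_dim: int, units: int, activation: str,
                 rng: np.random.Generator, dtype=np.float64):
        if activation not in ("relu", "linear"):
            raise ValueError("activation must be 'relu' or 'linear'")
        self.activation = activation
        self.W = glorot_uniform(rng, input_dim, units, (input_dim, units), dtype)
        self.b = np.zeros(units, dtype=dtype)
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        z = x @ self.W + self.b
        y = relu(z) if self.activation == "relu" else z
        if train:
            self._cache = (x, z)
        return y

    def backward(self, dy: np.ndarray):
        x, z = self._cache
        dz = dy * (z > 0) if self.activation == "relu" else dy
        dW = x.T @ dz
        db = dz.sum(axis=0)
        dx = dz @ self.W.T
        return dx, [dW, db]


def _sigmoid_fast(x: np.ndarray) -> np.ndarray:
    # plain logistic; exp overflow for very negative inputs still yields the
    # correct limit (0), so only the warning needs suppressing
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


class LSTM:
    """Single LSTM layer; gate layout (i, f, o, g) along the last axis
    (the three logistic gates are contiguous so one vectorized call
    squashes them all).

    `forward` returns the full hidden sequence plus the final (h, c) pair;
    `backward` accepts a gradient for the hidden sequence and/or for the
    final states (the second encoder layer's final h and c both feed the
    latent vector).
    """

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.units = units
        self.Wx = glorot_uniform(rng, input_dim, units, (input_dim, 4 * units),
                                 dtype)
        self.Wh = glorot_uniform(rng, units, units, (units, 4 * units), dtype)
        self.b = np.zeros(4 * units, dtype=dtype)
        self.b[units:2 * units] = 1.0  # forget-gate bias
        self._cache = None

    @property
    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray, train: bool = False):
        B, T, _ = X.shape
        U = self.units
        dt = self.Wx.dtype
        h = np.zeros((B, U), dtype=dt)
        c = np.zeros((B, U), dtype=dt)
        H_seq = np.empty((B, T, U), dtype=dt)
        # input projection for all timesteps in one matmul
        XWx = (X.reshape(B * T, -1) @ self.Wx).reshape(B, T, 4 * U)
        cache = [] if train else None
        for t in range(T):
            z = XWx[:, t] + h @ self.Wh + self.b
            gates = _sigmoid_fast(z[:, :3 * U])
            i = gates[:, :U]
            f = gates[:, U:2 * U]
            o = gates[:, 2 * U:]
            g = np.tanh(z[:, 3 * U:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            H_seq[:, t, :] = h
            if train:
                cache.append((h_prev, c_prev, i, f, g, o, tc))
        if train:
            self._cache = (cache, X)
        return H_seq, (h, c)

    def backward(self, dH_seq=None, dh_last=None, dc_last=None):
        cache, X = self._cache
        B, T, D = X.shape
        U = self.units
        dt = self.Wx.dtype
        dWh = np.zeros_like(self.Wh)
        dZ = np.empty((B, T, 4 * U), dtype=dt)
        dh_next = np.zeros((B, U), dtype=dt) if dh_last is None \
            else dh_last.astype(dt)
        dc_next = np.zeros((B, U), dtype=dt) if dc_last is None \
            else dc_last.astype(dt)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = dh_next
            if dH_seq is not None:
                dh = dh + dH_seq[:, t, :]
            dc = dc_next + dh * o * (1.0 - tc * tc)
            do = dh * tc
            dz = np.empty((B, 4 * U), dtype=dt)
            dz[:, :U] = (dc * g) * i * (1.0 - i)
            dz[:, U:2 * U] = (dc * c_prev) * f * (1.0 - f)
            dz[:, 2 * U:3 * U] = do * o * (1.0 - o)
            dz[:, 3 * U:] = (dc * i) * (1.0 - g * g)
            dWh += h_prev.T @ dz
            dZ[:, t, :] = dz
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        # weight/input gradients batched over all timesteps
        dZ_flat = dZ.reshape(B * T, 4 * U)
        dWx = X.reshape(B * T, D).T @ dZ_flat
        db = dZ_flat.sum(axis=0)
        dX = (dZ_flat @ self.Wx.T).reshape(B, T, D)
        return dX, [dWx, dWh, db]


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updates in place)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
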