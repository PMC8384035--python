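"""Compact numpy sequence-model toolkit: LSTM, dense layers, dropout, Adam.

The gait decoder's networks are small (hidden sizes 20-60), so plain numpy
matrix algebra trains them comfortably on one CPU. Layers operate on
time-major arrays of shape (T, B, D) and implement explicit forward/backward
passes; backpropagation through time is exact.

Conventions: LSTM gate order is (input, forget, cell, output); forget-gate
bias initialised to 1; Glorot-uniform weight initialisation; inverted dropout.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Param:
    """A weight array with its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = value
        self.g = np.zeros_like(value)


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class LSTM(Layer):
    """Single LSTM layer over a (T, B, D) sequence, returning (T, B, H)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.in_dim = in_dim
        self.hidden = hidden
        self.Wx = Param(_glorot(rng, (in_dim, 4 * hidden)))
        self.Wh = Param(_glorot(rng, (hidden, 4 * hidden)))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Param(b)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        T, B, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((T, B, H))
        cache = []
        for t in range(T):
            z = x[t] @ self.Wx.v + h @ self.Wh.v + self.b.v
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[t] = h
            if training:
                cache.append((x[t], i, f, g, o, c_prev, tc))
        self._cache = (cache, x.shape) if training else None
        return hs

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cache, x_shape = self._cache
        T, B, _ = x_shape
        H = self.hidden
        dx = np.empty(x_shape)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        # h_prev at step t is h from step t-1
        for t in range(T - 1, -1, -1):
            x_t, i, f, g, o, c_prev, tc = cache[t]
            dh = dy[t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            h_prev = cache[t - 1][4] * cache[t - 1][6] if t > 0 else np.zeros((B, H))
            self.Wx.g += x_t.T @ dz
            self.Wh.g += h_prev.T @ dz
            self.b.g += dz.sum(axis=0)
            dx[t] = dz @ self.Wx.v.T
            dh_next = dz @ self.Wh.v.T
        self._cache = None
        return dx


class Dense(Layer):
    """Time-distributed affine layer with optional ReLU."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 relu: bool = False):
        self.W = Param(_glorot(rng, (in_dim, out_dim)))
        self.b = Param(np.zeros(out_dim))
        self.relu = relu
        self._x = None
        self._mask = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = x @ self.W.v + self.b.v
        if self.relu:
            self._mask = y > 0
            y = np.where(self._mask, y, 0.0)
        if training:
            self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = np.where(self._mask, dy, 0.0)
        x = self._x
        T, B, D = x.shape
        x2 = x.reshape(T * B, D)
        dy2 = dy.reshape(T * B, -1)
        self.W.g += x2.T @ dy2
        self.b.g += dy2.sum(axis=0)
        dx = dy2 @ self.W.v.T
        self._x = None
        return dx.reshape(T, B, D)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.p == 0.0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sequential:
    """A stack of layers sharing one forward/backward interface."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def zero_grad(self) -> None:
        for p in self.params():
            p.g[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        return [p.v.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.v[...] = w


class Adam:
    """Adam optimiser over a parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clip: float = 5.0):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.clip = clip
        self.m = [np.zeros_like(p.v) for p in params]
        self.s = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        if self.clip:
            norm = np.sqrt(sum(float(np.sum(p.g * p.g)) for p in self.params))
            if norm > self.clip:
                scale = self.clip / (norm + 1e-12)
                for p in self.params:
                    p.g *= scale
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, s in zip(self.params, self.m, self.s):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * p.g
            s[...] = self.beta2 * s + (1.0 - self.beta2) * p.g * p.g
            p.v -= self.lr * (m / b1t) / (np.sqrt(s / b2t) + self.eps)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over all (T, B) steps; returns (loss, dlogits)."""
    p = softmax(logits)
    T, B, C = logits.shape
    flat = p.reshape(T * B, C)
    lab = labels.reshape(T * B)
    n = T * B
    loss = -float(np.mean(np.log(flat[np.arange(n), lab] + 1e-12)))
    d = flat.copy()
    d[np.arange(n), lab] -= 1.0
    return loss, (d / n).reshape(T, B, C)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all steps; pred (T, B, 1), target (T, B)."""
    diff = pred[..., 0] - target
    loss = float(np.mean(diff * diff))
    d = (2.0 * diff / diff.size)[..., None]
    return loss, d


def fit_network(
    net: Sequential,
    X: np.ndarray,
    Y: np.ndarray,
    loss_fn,
    *,
    lr: float = 1e-3,
    epochs: int = 30,
    batch_size: int = 64,
    seed: int = 0,
    val_fraction: float = 0.1,
    patience: int = 8,
    optimizer: Adam | None = None,
) -> dict:
    """Mini-batch training of sequence data X (N, T, D) against targets Y.

    Y is (N, T) — integer labels for classification, floats for regression.
    A tail fraction of the sequences is held out for early stopping; the best
    validation weights are restored at the end. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    N = X.shape[0]
    n_val = int(val_fraction * N) if val_fraction > 0 and N >= 20 else 0
    if n_val:
        perm = rng.permutation(N)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xv, Yv = X[val_idx], Y[val_idx]
        Xt, Yt = X[tr_idx], Y[tr_idx]
    else:
        Xt, Yt = X, Y
        Xv = Yv = None
    opt = optimizer if optimizer is not None else Adam(net.params(), lr=lr)
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = None
    bad = 0
    for _epoch in range(epochs):
        order = rng.permutation(len(Xt))
        losses = []
        for k in range(0, len(order), batch_size):
            idx = order[k : k + batch_size]
            xb = np.transpose(Xt[idx], (1, 0, 2))
            yb = Yt[idx].T
            net.zero_grad()
            out = net.forward(xb, training=True)
            loss, dout = loss_fn(out, yb)
            net.backward(dout)
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if Xv is not None:
            out = net.forward(np.transpose(Xv, (1, 0, 2)), training=False)
            vloss, _ = loss_fn(out, Yv.T)
            history["val_loss"].append(vloss)
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_weights = net.get_weights()
                bad = 0
            else:
                bad += 1
                if patience and bad >= patience:
                    break
    if best_weights is not None:
        net.set_weights(best_weights)
    return history
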