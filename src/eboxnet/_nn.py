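"""Minimal NumPy neural-network engine used by the classifiers.

Layers carry their own parameters and forward caches; gradients are written
by explicit backward passes and verified against finite differences in the
test suite. Everything is float32 and fully deterministic given the seeds
passed in.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Adam:
    """Adaptive-moment gradient descent (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: dict[str, Param], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p in self.params.values():
            if self.weight_decay and p.value.ndim > 1:  # decay matrices, not biases
                p.grad += self.weight_decay * p.value
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad * p.grad
            p.value -= (self.lr * (p.m / bias1) /
                        (np.sqrt(p.v / bias2) + self.eps)).astype(F32)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad[...] = 0.0


def glorot(rng: np.random.Generator, shape: tuple[int, ...],
           fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


# one-hot lookup with row 4 (N) spread uniformly
ONE_HOT5 = np.vstack([np.eye(4, dtype=F32), np.full((1, 4), 0.25, dtype=F32)])


class ConvOneHot:
    """1-D convolution over a one-hot (or N-softened) DNA sequence.

    Weights are stored flat as (4*width, n_filters) with row index
    base*width + position, so ``filters`` returns (n_filters, 4, width).
    """

    def __init__(self, width: int, n_filters: int, rng: np.random.Generator):
        self.width = width
        self.n_filters = n_filters
        self.W = Param(glorot(rng, (4 * width, n_filters), 4 * width, n_filters))
        self._xcol: np.ndarray | None = None

    @property
    def filters(self) -> np.ndarray:
        return self.W.value.T.reshape(self.n_filters, 4, self.width)

    def forward(self, codes: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        # codes: (B, L) uint8 -> response (B, T, F), T = L - width + 1
        win = np.lib.stride_tricks.sliding_window_view(codes, self.width, axis=1)
        xcol = ONE_HOT5[win]                    # (B, T, width, 4)
        B, T = xcol.shape[:2]
        xcol = np.ascontiguousarray(xcol.transpose(0, 1, 3, 2)).reshape(B, T, 4 * self.width)
        if keep_cache:
            self._xcol = xcol
        return xcol @ self.W.value

    def backward(self, dz: np.ndarray) -> None:
        B, T, F = dz.shape
        xf = self._xcol.reshape(B * T, 4 * self.width)
        self.W.grad += xf.T @ dz.reshape(B * T, F)
        self._xcol = None


class ConvDense:
    """1-D convolution over a dense (B, T0, D) input (embedding channels)."""

    def __init__(self, width: int, d_in: int, n_filters: int, rng: np.random.Generator):
        self.width = width
        self.d_in = d_in
        self.n_filters = n_filters
        self.W = Param(glorot(rng, (width * d_in, n_filters), width * d_in, n_filters))
        self._xcol: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        win = np.lib.stride_tricks.sliding_window_view(x, self.width, axis=1)  # (B,T,D,w)
        B, T = win.shape[:2]
        xcol = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, T, self.width * self.d_in)
        if keep_cache:
            self._xcol = xcol
            self._in_shape = x.shape
        return xcol @ self.W.value

    def backward(self, dz: np.ndarray) -> np.ndarray:
        B, T, F = dz.shape
        xf = self._xcol.reshape(B * T, -1)
        self.W.grad += xf.T @ dz.reshape(B * T, F)
        dxcol = (dz.reshape(B * T, F) @ self.W.value.T).reshape(B, T, self.width, self.d_in)
        dx = np.zeros(self._in_shape, dtype=F32)
        for j in range(self.width):
            dx[:, j : j + T, :] += dxcol[:, :, j, :]
        self._xcol = None
        return dx


class Embedding:
    def __init__(self, vocab: int, dim: int, rng: np.random.Generator):
        self.E = Param(rng.normal(0.0, 0.1, size=(vocab, dim)).astype(F32))
        self._idx: np.ndarray | None = None

    def forward(self, idx: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        if keep_cache:
            self._idx = idx
        return self.E.value[idx]

    def backward(self, dx: np.ndarray) -> None:
        np.add.at(self.E.grad, self._idx, dx)
        self._idx = None


class ThresholdReLU:
    """DeepBind-style rectifier max(0, x - b) with a learnable threshold b
    per filter."""

    def __init__(self, n_filters: int):
        self.b = Param(np.zeros(n_filters, dtype=F32))
        self._mask: np.ndarray | None = None

    def forward(self, z: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        a = np.maximum(z - self.b.value, 0.0)
        if keep_cache:
            self._mask = a > 0
        return a

    def backward(self, da: np.ndarray) -> np.ndarray:
        dz = da * self._mask
        self.b.grad += -dz.sum(axis=tuple(range(dz.ndim - 1)))
        self._mask = None
        return dz


class GlobalPool:
    """'max' or 'max_and_avg' pooling over the position axis of (B, T, F)."""

    def __init__(self, mode: str):
        if mode not in ("max", "max_and_avg"):
            raise ValueError(f"unsupported pooling mode {mode!r}")
        self.mode = mode
        self._argmax: np.ndarray | None = None
        self._shape: tuple | None = None

    def out_features(self, n_filters: int) -> int:
        return 2 * n_filters if self.mode == "max_and_avg" else n_filters

    def forward(self, a: np.ndarray) -> np.ndarray:
        self._shape = a.shape
        self._argmax = a.argmax(axis=1)  # (B, F)
        mx = np.take_along_axis(a, self._argmax[:, None, :], axis=1)[:, 0, :]
        if self.mode == "max":
            return mx
        return np.concatenate([mx, a.mean(axis=1)], axis=1)

    def backward(self, d: np.ndarray) -> np.ndarray:
        B, T, F = self._shape
        da = np.zeros(self._shape, dtype=F32)
        dmx = d[:, :F]
        np.put_along_axis(da, self._argmax[:, None, :], dmx[:, None, :], axis=1)
        if self.mode == "max_and_avg":
            da += (d[:, F:] / T)[:, None, :]
        self._argmax = None
        return da


class LocalMaxPool:
    """Non-overlapping max pooling of width = stride over the position axis
    of (B, T, F); trailing positions that do not fill a window are dropped."""

    def __init__(self, stride: int):
        if stride < 1:
            raise ValueError("pool stride must be >= 1")
        self.stride = stride
        self._argmax: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, a: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        if self.stride == 1:
            self._shape = None
            return a
        B, T, F = a.shape
        Tp = T // self.stride
        blocks = a[:, : Tp * self.stride, :].reshape(B, Tp, self.stride, F)
        am = blocks.argmax(axis=2)  # (B, Tp, F)
        out = np.take_along_axis(blocks, am[:, :, None, :], axis=2)[:, :, 0, :]
        if keep_cache:
            self._argmax = am
            self._shape = (B, T, F)
        return out

    def backward(self, d: np.ndarray) -> np.ndarray:
        if self.stride == 1 or self._shape is None:
            return d
        B, T, F = self._shape
        Tp = d.shape[1]
        da = np.zeros((B, Tp, self.stride, F), dtype=F32)
        np.put_along_axis(da, self._argmax[:, :, None, :], d[:, :, None, :], axis=2)
        out = np.zeros((B, T, F), dtype=F32)
        out[:, : Tp * self.stride, :] = da.reshape(B, Tp * self.stride, F)
        self._argmax = None
        return out


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Param(glorot(rng, (d_in, d_out), d_in, d_out))
        self.b = Param(np.zeros(d_out, dtype=F32))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        if keep_cache:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, d: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ d
        self.b.grad += d.sum(axis=0)
        dx = d @ self.W.value.T
        self._x = None
        return dx


class ReLU:
    """Rectifier for the classifier head; a small leak keeps gradient alive
    so the fully connected units cannot die irrecoverably."""

    def __init__(self, leak: float = 0.1):
        self.leak = leak
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        if keep_cache:
            self._mask = x > 0
        return np.where(x > 0, x, self.leak * x)

    def backward(self, d: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, d, self.leak * d)
        self._mask = None
        return out


class Dropout:
    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout_p {p} outside [0, 1)")
        self.p = p
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p).astype(F32) / (1.0 - self.p)
        return x * self._mask

    def backward(self, d: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return d
        out = d * self._mask
        self._mask = None
        return out


class LSTM:
    """Single LSTM layer, batch-major (B, T, D) -> (B, T, H).

    Gate order i, f, g, o; the forget-gate bias starts high (default 3, i.e.
    an initial forget gate of ~0.95) so credit can flow across many timesteps
    before the gates are learned.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 forget_bias: float = 3.0):
        self.d_in, self.hidden = d_in, hidden
        self.Wx = Param(glorot(rng, (d_in, 4 * hidden), d_in, 4 * hidden))
        self.Wh = Param(glorot(rng, (hidden, 4 * hidden), hidden, 4 * hidden))
        b = np.zeros(4 * hidden, dtype=F32)
        b[hidden : 2 * hidden] = forget_bias
        self.b = Param(b)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        B, T, D = x.shape
        H = self.hidden
        xp = (x.reshape(B * T, D) @ self.Wx.value).reshape(B, T, 4 * H) + self.b.value
        I = np.empty((T, B, H), dtype=F32)
        Fg = np.empty_like(I)
        G = np.empty_like(I)
        O = np.empty_like(I)
        C = np.empty_like(I)
        TC = np.empty_like(I)
        hout = np.empty((B, T, H), dtype=F32)
        h = np.zeros((B, H), dtype=F32)
        c = np.zeros((B, H), dtype=F32)
        Wh = self.Wh.value
        for t in range(T):
            g = xp[:, t, :] + h @ Wh
            I[t] = sigmoid(g[:, :H])
            Fg[t] = sigmoid(g[:, H : 2 * H])
            G[t] = np.tanh(g[:, 2 * H : 3 * H])
            O[t] = sigmoid(g[:, 3 * H :])
            c = Fg[t] * c + I[t] * G[t]
            C[t] = c
            TC[t] = np.tanh(c)
            h = O[t] * TC[t]
            hout[:, t, :] = h
        if keep_cache:
            self._cache = (x, I, Fg, G, O, C, TC, hout)
        return hout

    def backward(self, dh_out: np.ndarray) -> np.ndarray:
        x, I, Fg, G, O, C, TC, hout = self._cache
        B, T, D = x.shape
        H = self.hidden
        Wh = self.Wh.value
        dxp = np.empty((B, T, 4 * H), dtype=F32)
        dWh = np.zeros_like(Wh)
        dh = np.zeros((B, H), dtype=F32)
        dc = np.zeros((B, H), dtype=F32)
        for t in range(T - 1, -1, -1):
            dht = dh_out[:, t, :] + dh
            do = dht * TC[t]
            dc = dc + dht * O[t] * (1.0 - TC[t] * TC[t])
            di = dc * G[t]
            c_prev = C[t - 1] if t > 0 else np.zeros((B, H), dtype=F32)
            df = dc * c_prev
            dg = dc * I[t]
            dgate = np.concatenate([
                di * I[t] * (1 - I[t]),
                df * Fg[t] * (1 - Fg[t]),
                dg * (1 - G[t] * G[t]),
                do * O[t] * (1 - O[t]),
            ], axis=1)
            dxp[:, t, :] = dgate
            h_prev = hout[:, t - 1, :] if t > 0 else np.zeros((B, H), dtype=F32)
            dWh += h_prev.T @ dgate
            dh = dgate @ Wh.T
            dc = dc * Fg[t]
        self.Wh.grad += dWh
        self.b.grad += dxp.sum(axis=(0, 1))
        dxp_flat = dxp.reshape(B * T, 4 * H)
        self.Wx.grad += x.reshape(B * T, D).T @ dxp_flat
        dx = (dxp_flat @ self.Wx.value.T).reshape(B, T, D)
        self._cache = None
        return dx
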