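"""Layers with forward/backward passes.

Data layout is channels-last: images are (N, H, W, C), sequences (N, T, D).
Each layer exposes ``params`` / ``grads`` as parallel lists of arrays so the
optimizer can update in place, and caches whatever the backward pass needs
only when ``train=True``.
"""

from __future__ import annotations

import numpy as np


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
                   fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Conv2D(Layer):
    """3x3 (or k x k) convolution with 'same' zero padding, stride 1.

    Evaluated as a sum of per-offset matrix products on shifted views of the
    zero-padded input — equivalent to im2col + one big GEMM, but it never
    materializes the k*k-times-redundant column matrix, which on a single
    core costs more in memory traffic than the arithmetic itself.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, *,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = kernel * kernel * c_in
        fan_out = kernel * kernel * c_out
        # weight rows follow the (ki, kj, c_in) flattening
        self.W = glorot_uniform(rng, (fan_in, c_out), fan_in, fan_out, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._cache = None

    def _w_offset(self, i: int, j: int) -> np.ndarray:
        c = self.c_in
        o = (i * self.k + j) * c
        return self.W[o:o + c]  # (c_in, c_out) block for kernel offset (i, j)

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=self.W.dtype)
        n, h, w, c = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        w2 = w + 2 * p
        y = np.tile(self.b, (n, h, w, 1))
        for i in range(k):
            band = xp[:, i:i + h].reshape(n, h * w2, c)  # contiguous view
            for j in range(k):
                z = np.matmul(band, self._w_offset(i, j)).reshape(n, h, w2, self.c_out)
                y += z[:, :, j:j + w, :]
        if train:
            self._cache = (xp, x.shape)
        return y

    def backward(self, dy):
        xp, xshape = self._cache
        n, h, w, c = xshape
        k, p = self.k, self.k // 2
        dy = np.ascontiguousarray(dy, dtype=self.W.dtype)
        dyf = dy.reshape(-1, self.c_out)
        self.grads[1][...] = dyf.sum(axis=0)
        dW = self.grads[0]
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                xs = np.ascontiguousarray(xp[:, i:i + h, j:j + w, :]).reshape(-1, c)
                o = (i * k + j) * c
                dW[o:o + c] = xs.T @ dyf
                dxp[:, i:i + h, j:j + w, :] += (dyf @ self._w_offset(i, j).T).reshape(
                    n, h, w, c
                )
        self._cache = None
        return dxp[:, p:p + h, p:p + w, :]


class ReLU(Layer):
    def forward(self, x, train=False):
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2. Requires even spatial dimensions."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        r = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        r = r.reshape(n, h // 2, w // 2, c, 4)
        idx = r.argmax(axis=-1)
        y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._xshape = idx, x.shape
        return y

    def backward(self, dy):
        n, h, w, c = self._xshape
        dr = np.zeros((n, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(dr, self._idx[..., None], dy[..., None], axis=-1)
        dr = dr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dr.reshape(n, h, w, c)


class Flatten(Layer):
    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class ToSequence(Layer):
    """Re-read a (N, H, W, C) feature map as a sequence along the time axis:
    each of the W time columns becomes one step with an H*C feature vector."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        if train:
            self._shape = x.shape
        return np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(n, w, h * c)

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.ascontiguousarray(dy.reshape(n, w, h, c).transpose(0, 2, 1, 3))


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, *, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.W = glorot_uniform(rng, (d_in, d_out), d_in, d_out, dtype)
        self.b = np.zeros(d_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=self.W.dtype)
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        dy = np.ascontiguousarray(dy, dtype=self.W.dtype)
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class LSTM(Layer):
    """One LSTM layer, single-bias parameterization: 4*(d*u + u^2 + u) params.

    Gate order in the fused weight matrices is (input, forget, cell, output);
    the forget-gate bias starts at 1 so early training does not flush state.
    """

    def __init__(self, d_in: int, units: int, *, return_sequences: bool = False,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        u = units
        self.d_in, self.units = d_in, u
        self.return_sequences = return_sequences
        self.Wx = glorot_uniform(rng, (d_in, 4 * u), d_in, 4 * u, dtype)
        self.Wh = glorot_uniform(rng, (u, 4 * u), u, 4 * u, dtype)
        self.b = np.zeros(4 * u, dtype=dtype)
        self.b[u:2 * u] = 1.0
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=self.Wx.dtype)
        n, T, _ = x.shape
        u = self.units
        h = np.zeros((n, u), dtype=x.dtype)
        c = np.zeros((n, u), dtype=x.dtype)
        hs = np.empty((n, T, u), dtype=x.dtype)
        caches = []
        for t in range(T):
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = _sigmoid(z[:, 3 * u:])
            c_new = f * c + i * g
            hc = np.tanh(c_new)
            h_new = o * hc
            if train:
                caches.append((x[:, t], h, c, i, f, g, o, hc))
            h, c = h_new, c_new
            hs[:, t] = h
        if train:
            self._caches, self._T, self._n = caches, T, n
        return hs if self.return_sequences else h

    def backward(self, dy):
        u, T, n = self.units, self._T, self._n
        dt = self.Wx.dtype
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.empty((n, T, self.d_in), dtype=dt)
        dh_next = np.zeros((n, u), dtype=dt)
        dc_next = np.zeros((n, u), dtype=dt)
        for t in reversed(range(T)):
            x_t, h_prev, c_prev, i, f, g, o, hc = self._caches[t]
            if self.return_sequences:
                dh = dh_next + np.ascontiguousarray(dy[:, t], dtype=dt)
            else:
                dh = dh_next + (np.ascontiguousarray(dy, dtype=dt) if t == T - 1 else 0.0)
            do = dh * hc
            dc = dc_next + dh * o * (1 - hc**2)
            di, dg, df = dc * g, dc * i, dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
        self.grads[0][...] = dWx
        self.grads[1][...] = dWh
        self.grads[2][...] = db
        self._caches = None
        return dx
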