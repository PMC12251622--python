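"""Neural-network building blocks in NumPy.

Each layer implements ``forward(x, training)`` and ``backward(dout)``;
``backward`` returns the gradient with respect to the layer input and
accumulates parameter gradients into each :class:`Param`.  Layers cache the
forward intermediates they need, so a backward call must follow the matching
forward call.  All computation defaults to float32; float64 is available for
numerical gradient checking.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Dense(Layer):
    """Affine map (B, n_in) -> (B, n_out)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32, name="dense"):
        self.W = Param(_glorot(rng, (n_in, n_out), n_in, n_out, dtype), f"{name}.W")
        self.b = Param(np.zeros(n_out, dtype=dtype), f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class BatchNorm(Layer):
    """Batch normalization over the batch (and length) axes.

    Accepts (B, F) or (B, C, L); statistics are taken per feature/channel.
    Running statistics are used at inference.
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5, dtype=np.float32, name="bn"):
        self.gamma = Param(np.ones(n_features, dtype=dtype), f"{name}.gamma")
        self.beta = Param(np.zeros(n_features, dtype=dtype), f"{name}.beta")
        self.running_mean = np.zeros(n_features, dtype=dtype)
        self.running_var = np.ones(n_features, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def _axes_and_shape(self, x):
        if x.ndim == 2:
            return (0,), (1, -1)
        if x.ndim == 3:  # (B, C, L), stats per channel
            return (0, 2), (1, -1, 1)
        raise ValueError("BatchNorm expects 2-D or 3-D input")

    def forward(self, x, training=False):
        axes, shape = self._axes_and_shape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        self._cache = (xhat, inv_std, axes, shape)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, dout):
        xhat, inv_std, axes, shape = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = self.gamma.value.reshape(shape)
        dxhat = dout * g
        # standard batch-norm input gradient
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * inv_std.reshape(shape)
        return dx


class Conv1D(Layer):
    """1-D convolution, stride 1, 'same' zero padding: (B, C_in, L) -> (B, C_out, L)."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng, dtype=np.float32, name="conv"):
        fan_in = c_in * kernel_size
        self.W = Param(
            _glorot(rng, (c_out, c_in, kernel_size), fan_in, c_out, dtype), f"{name}.W"
        )
        self.b = Param(np.zeros(c_out, dtype=dtype), f"{name}.b")
        self.k = kernel_size

    def params(self):
        return [self.W, self.b]

    def _im2col(self, x):
        B, C, L = x.shape
        k = self.k
        left = (k - 1) // 2
        right = k - 1 - left
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
        cols = np.empty((B, L, C * k), dtype=x.dtype)
        for j in range(k):
            cols[:, :, j * C : (j + 1) * C] = xp[:, :, j : j + L].transpose(0, 2, 1)
        return cols, (left, right)

    def forward(self, x, training=False):
        B, C, L = x.shape
        cols, pad = self._im2col(x)  # (B, L, C*k)
        self._cols, self._shape, self._pad = cols, x.shape, pad
        # weight as (C*k, C_out) matching the im2col layout (tap-major)
        Wmat = self.W.value.transpose(2, 1, 0).reshape(self.k * C, -1)
        out = cols.reshape(B * L, -1) @ Wmat + self.b.value
        return out.reshape(B, L, -1).transpose(0, 2, 1)

    def backward(self, dout):
        B, C, L = self._shape
        k = self.k
        dmat = dout.transpose(0, 2, 1).reshape(B * L, -1)  # (B*L, C_out)
        cols = self._cols.reshape(B * L, -1)
        dW = cols.T @ dmat  # (C*k, C_out)
        self.W.grad += dW.reshape(k, C, -1).transpose(2, 1, 0)
        self.b.grad += dmat.sum(axis=0)
        Wmat = self.W.value.transpose(2, 1, 0).reshape(k * C, -1)
        dcols = (dmat @ Wmat.T).reshape(B, L, k, C)
        left, right = self._pad
        dxp = np.zeros((B, C, L + left + right), dtype=dout.dtype)
        for j in range(k):
            dxp[:, :, j : j + L] += dcols[:, :, j, :].transpose(0, 2, 1)
        return dxp[:, :, left : left + L]


class GlobalAvgPool1D(Layer):
    """(B, C, L) -> (B, C)."""

    def forward(self, x, training=False):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout):
        return np.repeat(dout[:, :, None], self._L, axis=2) / self._L


class LSTM(Layer):
    """Unidirectional LSTM over (B, T, I) with fused BPTT.

    Gate order in the packed weight matrices is (input, forget, cell, output).
    Returns the full hidden sequence (B, T, H).
    """

    def __init__(self, n_in: int, n_hidden: int, rng, dtype=np.float32, name="lstm"):
        H = n_hidden
        self.W = Param(_glorot(rng, (n_in, 4 * H), n_in + H, 4 * H, dtype), f"{name}.W")
        self.U = Param(_glorot(rng, (H, 4 * H), n_in + H, 4 * H, dtype), f"{name}.U")
        b = np.zeros(4 * H, dtype=dtype)
        b[H : 2 * H] = 1.0  # forget-gate bias
        self.b = Param(b, f"{name}.b")
        self.H = H

    def params(self):
        return [self.W, self.U, self.b]

    def forward(self, x, training=False):
        B, T, I = x.shape
        H = self.H
        xp = (x.reshape(B * T, I) @ self.W.value).reshape(B, T, 4 * H) + self.b.value
        hs = np.empty((B, T, H), dtype=x.dtype)
        cs = np.empty((B, T, H), dtype=x.dtype)
        gates = np.empty((B, T, 4 * H), dtype=x.dtype)
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        U = self.U.value
        for t in range(T):
            a = xp[:, t] + h @ U
            ai, af, ag, ao = a[:, :H], a[:, H : 2 * H], a[:, 2 * H : 3 * H], a[:, 3 * H :]
            i_g = 1.0 / (1.0 + np.exp(-ai))
            f_g = 1.0 / (1.0 + np.exp(-af))
            g_g = np.tanh(ag)
            o_g = 1.0 / (1.0 + np.exp(-ao))
            c = f_g * c + i_g * g_g
            h = o_g * np.tanh(c)
            gates[:, t, :H] = i_g
            gates[:, t, H : 2 * H] = f_g
            gates[:, t, 2 * H : 3 * H] = g_g
            gates[:, t, 3 * H :] = o_g
            cs[:, t] = c
            hs[:, t] = h
        self._cache = (x, gates, cs, hs)
        return hs

    def backward(self, dhs):
        x, gates, cs, hs = self._cache
        B, T, I = x.shape
        H = self.H
        U = self.U.value
        da_all = np.empty((B, T, 4 * H), dtype=x.dtype)
        dh_next = np.zeros((B, H), dtype=x.dtype)
        dc_next = np.zeros((B, H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            i_g = gates[:, t, :H]
            f_g = gates[:, t, H : 2 * H]
            g_g = gates[:, t, 2 * H : 3 * H]
            o_g = gates[:, t, 3 * H :]
            c = cs[:, t]
            tanh_c = np.tanh(c)
            dh = dhs[:, t] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o_g * (1.0 - tanh_c**2)
            di = dc * g_g
            dg = dc * i_g
            c_prev = cs[:, t - 1] if t > 0 else np.zeros_like(c)
            df = dc * c_prev
            dc_next = dc * f_g
            da = np.empty((B, 4 * H), dtype=x.dtype)
            da[:, :H] = di * i_g * (1.0 - i_g)
            da[:, H : 2 * H] = df * f_g * (1.0 - f_g)
            da[:, 2 * H : 3 * H] = dg * (1.0 - g_g**2)
            da[:, 3 * H :] = do * o_g * (1.0 - o_g)
            da_all[:, t] = da
            dh_next = da @ U.T
        # parameter gradients, batched over time
        flat_da = da_all.reshape(B * T, 4 * H)
        self.W.grad += x.reshape(B * T, I).T @ flat_da
        h_prev = np.concatenate(
            [np.zeros((B, 1, H), dtype=x.dtype), hs[:, :-1]], axis=1
        ).reshape(B * T, H)
        self.U.grad += h_prev.T @ flat_da
        self.b.grad += flat_da.sum(axis=0)
        return (flat_da @ self.W.value.T).reshape(B, T, I)


class BiLSTM(Layer):
    """Bidirectional LSTM: forward and time-reversed passes concatenated.

    ``return_sequences=True`` yields (B, T, 2H); otherwise the last time step
    (B, 2H), i.e. the forward state at t=T-1 and the backward state at t=0.
    """

    def __init__(self, n_in, n_hidden, rng, return_sequences=True, dtype=np.float32, name="bilstm"):
        self.fwd = LSTM(n_in, n_hidden, rng, dtype, name=f"{name}.fwd")
        self.bwd = LSTM(n_in, n_hidden, rng, dtype, name=f"{name}.bwd")
        self.return_sequences = return_sequences
        self.H = n_hidden

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def forward(self, x, training=False):
        self._T = x.shape[1]
        hf = self.fwd.forward(x, training)
        hb = self.bwd.forward(x[:, ::-1], training)[:, ::-1]
        if self.return_sequences:
            return np.concatenate([hf, hb], axis=2)
        return np.concatenate([hf[:, -1], hb[:, 0]], axis=1)

    def backward(self, dout):
        H, T = self.H, self._T
        if self.return_sequences:
            dhf = np.ascontiguousarray(dout[:, :, :H])
            dhb = np.ascontiguousarray(dout[:, :, H:])
        else:
            B = dout.shape[0]
            dhf = np.zeros((B, T, H), dtype=dout.dtype)
            dhb = np.zeros((B, T, H), dtype=dout.dtype)
            dhf[:, -1] = dout[:, :H]
            dhb[:, 0] = dout[:, H:]
        dx_f = self.fwd.backward(dhf)
        dx_b = self.bwd.backward(dhb[:, ::-1])[:, ::-1]
        return dx_f + dx_b


class Adam:
    """Adam optimizer with the standard bias correction."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
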