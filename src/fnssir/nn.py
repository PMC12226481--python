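"""Minimal numpy neural-network layers with hand-written gradients.

The decoding network is built from these primitives: FFT-based 3D "same"
convolutions, per-row temporal 2D convolutions and transposed convolutions,
batch normalisation, average/max pooling, dropout, an LSTM, scaled
dot-product self-attention, and dense layers, trained with Adam on softmax
cross-entropy (plus an optional reconstruction MSE).  Every layer implements
``forward(x, training)`` and ``backward(dy)``; gradients are verified against
finite differences in the test suite.

All layers default to float32; pass ``dtype=np.float64`` for numerical
checks.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as sfft

__all__ = [
    "Parameter", "Layer", "Sequential", "Dense", "Conv3dSame", "Conv2dTime",
    "ConvTranspose2dTime", "BatchNorm", "ReLU", "Sigmoid", "AvgPool3d",
    "MaxPoolTime", "Dropout", "LSTM", "SelfAttention", "Flatten",
    "softmax_cross_entropy", "mse_loss", "Adam",
]


class Parameter:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def forward(self, x, training: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x, training: bool = False):
        return self.forward(x, training)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def _uniform(rng, shape, bound, dtype):
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32, name="dense"):
        bound = 1.0 / np.sqrt(n_in)
        self.W = Parameter(_uniform(rng, (n_in, n_out), bound, dtype), f"{name}.W")
        self.b = Parameter(np.zeros(n_out, dtype=dtype), f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += x2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        return dy @ self.W.value.T


class Conv3dSame(Layer):
    """3D convolution with odd kernels and "same" zero padding, via FFT.

    Input [B, C_in, H, W, T] -> [B, C_out, H, W, T].  ``first_layer=True``
    skips the input-gradient pass (the data needs no gradient).
    """

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int, int],
                 rng: np.random.Generator, first_layer: bool = False,
                 dtype=np.float32, name="conv3d"):
        if any(k % 2 == 0 for k in kernel):
            raise ValueError("same-padded 3D convolution needs odd kernel sizes")
        self.kernel = tuple(kernel)
        self.first_layer = first_layer
        fan_in = c_in * int(np.prod(kernel))
        bound = 1.0 / np.sqrt(fan_in)
        self.W = Parameter(_uniform(rng, (c_out, c_in) + self.kernel, bound, dtype),
                           f"{name}.W")
        self.b = Parameter(np.zeros(c_out, dtype=dtype), f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def _spectra(self, shape):
        kh, kw, kt = self.kernel
        H, W, T = shape
        S = tuple(sfft.next_fast_len(n + k - 1) for n, k in ((H, kh), (W, kw), (T, kt)))
        return S

    def forward(self, x, training=False):
        kh, kw, kt = self.kernel
        B, Ci, H, W, T = x.shape
        S = self._spectra((H, W, T))
        self._in_shape = x.shape
        Xf = sfft.rfftn(x, s=S, axes=(2, 3, 4))
        Wr = self.W.value[:, :, ::-1, ::-1, ::-1]
        Wf = sfft.rfftn(Wr, s=S, axes=(2, 3, 4))
        Yf = np.einsum("biuvw,oiuvw->bouvw", Xf, Wf, optimize=True)
        Yfull = sfft.irfftn(Yf, s=S, axes=(2, 3, 4))
        p = (kh // 2, kw // 2, kt // 2)
        y = Yfull[:, :, p[0]:p[0] + H, p[1]:p[1] + W, p[2]:p[2] + T]
        y = np.ascontiguousarray(y) + self.b.value[None, :, None, None, None]
        self._Xf, self._Wf, self._S = Xf, Wf, S
        return y

    def backward(self, dy):
        kh, kw, kt = self.kernel
        B, Ci, H, W, T = self._in_shape
        S = self._S
        p = (kh // 2, kw // 2, kt // 2)
        emb = np.zeros((dy.shape[0], dy.shape[1]) + S, dtype=dy.dtype)
        emb[:, :, p[0]:p[0] + H, p[1]:p[1] + W, p[2]:p[2] + T] = dy
        Ef = sfft.rfftn(emb, axes=(2, 3, 4))
        # weight gradient: circular correlation of input with the output grad
        Gf = np.einsum("biuvw,bouvw->oiuvw", np.conj(self._Xf), Ef, optimize=True)
        Gfull = sfft.irfftn(Gf, s=S, axes=(2, 3, 4))
        dWr = Gfull[:, :, :kh, :kw, :kt]
        self.W.grad += dWr[:, :, ::-1, ::-1, ::-1]
        self.b.grad += dy.sum(axis=(0, 2, 3, 4))
        if self.first_layer:
            return None
        Df = np.einsum("bouvw,oiuvw->biuvw", Ef, np.conj(self._Wf), optimize=True)
        Dfull = sfft.irfftn(Df, s=S, axes=(2, 3, 4))
        return np.ascontiguousarray(Dfull[:, :, :H, :W, :T])


def _spec_mul(A, B):
    """Frequency-domain contraction sum_i A[b,i,...] * B[o,i,...] -> [b,o,...].

    Specialised for the small channel counts used here: a single broadcast
    multiply when the contracted axis is 1, an accumulation loop otherwise
    (faster than complex einsum for these shapes).
    """
    nb, ni = A.shape[0], A.shape[1]
    no = B.shape[0]
    if ni == 1:
        return A[:, 0][:, None] * B[None, :, 0]
    out = A[:, 0][:, None] * B[None, :, 0]
    for i in range(1, ni):
        out += A[:, i][:, None] * B[None, :, i]
    return out


class MultiScaleConv3d(Layer):
    """Parallel same-padded 3D convolutions with different odd kernels, fused.

    Computes ``Cat(Conv_1(X), ..., Conv_g(X))`` over a shared FFT grid: one
    forward transform of the input serves every kernel, and all inverse
    transforms are batched.  Each kernel group keeps its own weight tensor
    (no cross-kernel support leakage), so the result is exactly the
    concatenation of independent same-padded convolutions.
    """

    def __init__(self, c_in: int, f_per_kernel: int, kernels, rng,
                 first_layer: bool = False, dtype=np.float32, name="msconv"):
        self.kernels = [tuple(k) for k in kernels]
        if any(k % 2 == 0 for kern in self.kernels for k in kern):
            raise ValueError("same-padded 3D convolution needs odd kernel sizes")
        self.f = f_per_kernel
        self.c_in = c_in
        self.first_layer = first_layer
        self.Ws = []
        for gi, kern in enumerate(self.kernels):
            fan_in = c_in * int(np.prod(kern))
            bound = 1.0 / np.sqrt(fan_in)
            self.Ws.append(Parameter(
                _uniform(rng, (f_per_kernel, c_in) + kern, bound, dtype),
                f"{name}.W{gi}"))
        self.b = Parameter(np.zeros(f_per_kernel * len(self.kernels), dtype=dtype),
                           f"{name}.b")

    def params(self):
        return self.Ws + [self.b]

    @property
    def c_out(self):
        return self.f * len(self.kernels)

    def forward(self, x, training=False):
        B, Ci, H, W, T = x.shape
        kmax = tuple(max(k[a] for k in self.kernels) for a in range(3))
        S = tuple(sfft.next_fast_len(n + k - 1)
                  for n, k in zip((H, W, T), kmax))
        self._in_shape, self._S = x.shape, S
        Xf = sfft.rfftn(x, s=S, axes=(2, 3, 4))
        Wr = np.zeros((self.c_out, Ci) + tuple(kmax), dtype=x.dtype)
        for gi, (kern, Wp) in enumerate(zip(self.kernels, self.Ws)):
            kh, kw, kt = kern
            Wr[gi * self.f:(gi + 1) * self.f, :, :kh, :kw, :kt] = \
                Wp.value[:, :, ::-1, ::-1, ::-1]
        Wf = sfft.rfftn(Wr, s=S, axes=(2, 3, 4))
        Yfull = sfft.irfftn(_spec_mul(Xf, Wf), s=S, axes=(2, 3, 4))
        y = np.empty((B, self.c_out, H, W, T), dtype=x.dtype)
        for gi, kern in enumerate(self.kernels):
            p = tuple(k // 2 for k in kern)
            y[:, gi * self.f:(gi + 1) * self.f] = Yfull[
                :, gi * self.f:(gi + 1) * self.f,
                p[0]:p[0] + H, p[1]:p[1] + W, p[2]:p[2] + T]
        y += self.b.value[None, :, None, None, None]
        self._Xf, self._Wf = Xf, Wf
        return y

    def backward(self, dy):
        B, Ci, H, W, T = self._in_shape
        S = self._S
        emb = np.zeros((B, self.c_out) + S, dtype=dy.dtype)
        for gi, kern in enumerate(self.kernels):
            p = tuple(k // 2 for k in kern)
            emb[:, gi * self.f:(gi + 1) * self.f,
                p[0]:p[0] + H, p[1]:p[1] + W, p[2]:p[2] + T] = \
                dy[:, gi * self.f:(gi + 1) * self.f]
        Ef = sfft.rfftn(emb, axes=(2, 3, 4))
        # weight gradients: circular correlation input (x) output-grad
        Xc = np.conj(self._Xf)
        Gf = np.zeros((self.c_out, Ci) + Ef.shape[2:], dtype=Ef.dtype)
        for b in range(B):
            for i in range(Ci):
                Gf[:, i] += Ef[b] * Xc[b, i][None]
        Gfull = sfft.irfftn(Gf, s=S, axes=(2, 3, 4))
        for gi, (kern, Wp) in enumerate(zip(self.kernels, self.Ws)):
            kh, kw, kt = kern
            dWr = Gfull[gi * self.f:(gi + 1) * self.f, :, :kh, :kw, :kt]
            Wp.grad += dWr[:, :, ::-1, ::-1, ::-1]
        self.b.grad += dy.sum(axis=(0, 2, 3, 4))
        if self.first_layer:
            return None
        Wc = np.conj(self._Wf)
        Df = np.zeros((B, Ci) + Ef.shape[2:], dtype=Ef.dtype)
        for o in range(self.c_out):
            for i in range(Ci):
                Df[:, i] += Ef[:, o] * Wc[o, i][None]
        Dfull = sfft.irfftn(Df, s=S, axes=(2, 3, 4))
        return np.ascontiguousarray(Dfull[:, :, :H, :W, :T])


class Conv2dTime(Layer):
    """Per-row temporal convolution: kernel (1, kt), same padding over time.

    Input [B, C_in, R, T] -> [B, C_out, R, T]; rows (electrodes) are not mixed.
    """

    def __init__(self, c_in: int, c_out: int, kt: int, rng: np.random.Generator,
                 dtype=np.float32, name="conv2d"):
        if kt % 2 == 0:
            raise ValueError("same padding needs an odd temporal kernel")
        self.kt = kt
        bound = 1.0 / np.sqrt(c_in * kt)
        self.W = Parameter(_uniform(rng, (c_out, c_in, kt), bound, dtype), f"{name}.W")
        self.b = Parameter(np.zeros(c_out, dtype=dtype), f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        p = self.kt // 2
        xp = np.pad(x, [(0, 0), (0, 0), (0, 0), (p, p)])
        V = sliding_window_view(xp, self.kt, axis=-1)  # [B,Ci,R,T,kt]
        self._V = V
        y = np.tensordot(V, self.W.value, axes=([1, 4], [1, 2]))  # [B,R,T,Co]
        return y.transpose(0, 3, 1, 2) + self.b.value[None, :, None, None]

    def backward(self, dy):
        p = self.kt // 2
        dW = np.tensordot(dy, self._V, axes=([0, 2, 3], [0, 2, 3]))  # [Co,Ci,kt]
        self.W.grad += dW
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dyp = np.pad(dy, [(0, 0), (0, 0), (0, 0), (p, p)])
        Vd = sliding_window_view(dyp, self.kt, axis=-1)  # [B,Co,R,T,kt]
        Wf = self.W.value[:, :, ::-1]
        dx = np.tensordot(Vd, Wf, axes=([1, 4], [0, 2]))  # [B,R,T,Ci]
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class ConvTranspose2dTime(Layer):
    """Temporal transposed convolution, kernel (1, kt), stride (1, s), pad (0, p).

    Output length (T-1)*s - 2p + kt; with kt=4, s=2, p=1 this doubles T exactly.
    """

    def __init__(self, c_in: int, c_out: int, kt: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator = None,
                 dtype=np.float32, name="convT"):
        self.kt, self.stride, self.pad = kt, stride, pad
        bound = 1.0 / np.sqrt(c_in * kt)
        self.W = Parameter(_uniform(rng, (c_in, c_out, kt), bound, dtype), f"{name}.W")
        self.b = Parameter(np.zeros(c_out, dtype=dtype), f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def out_len(self, T: int) -> int:
        return (T - 1) * self.stride - 2 * self.pad + self.kt

    def forward(self, x, training=False):
        B, Ci, R, T = x.shape
        Co = self.W.value.shape[1]
        To = self.out_len(T)
        self._x = x
        y = np.zeros((B, Co, R, To + 2 * self.pad), dtype=x.dtype)
        xc = np.tensordot(x, self.W.value, axes=([1], [0]))  # [B,R,T,Co,kt]
        for k in range(self.kt):
            y[:, :, :, k:k + self.stride * T:self.stride] += \
                xc[..., k].transpose(0, 3, 1, 2)
        y = y[:, :, :, self.pad:self.pad + To]
        return y + self.b.value[None, :, None, None]

    def backward(self, dy):
        B, Ci, R, T = self._x.shape
        dyp = np.pad(dy, [(0, 0), (0, 0), (0, 0), (self.pad, self.pad)])
        dxc = np.empty((B, R, T, dy.shape[1], self.kt), dtype=dy.dtype)
        for k in range(self.kt):
            dxc[..., k] = dyp[:, :, :, k:k + self.stride * T:self.stride] \
                .transpose(0, 2, 3, 1)
        # dx[b,i,r,t] = sum_{o,k} dxc[b,r,t,o,k] W[i,o,k]
        dx = np.tensordot(dxc, self.W.value, axes=([3, 4], [1, 2]))  # [B,R,T,Ci]
        self.W.grad += np.tensordot(self._x, dxc, axes=([0, 2, 3], [0, 1, 2]))
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class BatchNorm(Layer):
    """Normalisation over all axes except channel axis 1 (training: batch stats)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32, name="bn"):
        self.gamma = Parameter(np.ones(channels, dtype=dtype), f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=dtype), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def _bshape(self, ndim):
        return (1, -1) + (1,) * (ndim - 2)

    def forward(self, x, training=False):
        axes = (0,) + tuple(range(2, x.ndim))
        sh = self._bshape(x.ndim)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) / std.reshape(sh)
        self._cache = (xhat, std, axes, sh, training)
        return self.gamma.value.reshape(sh) * xhat + self.beta.value.reshape(sh)

    def backward(self, dy):
        xhat, std, axes, sh, training = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value.reshape(sh)
        if not training:
            return dy * g / std.reshape(sh)
        N = dy.size // dy.shape[1]
        dxhat = dy * g
        term = dxhat - dxhat.mean(axis=axes, keepdims=True) \
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        return term / std.reshape(sh)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class AvgPool3d(Layer):
    """Non-overlapping average pooling over [H, W, T]; extents must divide."""

    def __init__(self, pool: tuple[int, int, int]):
        self.pool = tuple(pool)

    def forward(self, x, training=False):
        B, C, H, W, T = x.shape
        p0, p1, p2 = self.pool
        if H % p0 or W % p1 or T % p2:
            raise ValueError(f"pool {self.pool} does not divide extents {(H, W, T)}")
        self._in_shape = x.shape
        y = x.reshape(B, C, H // p0, p0, W // p1, p1, T // p2, p2).mean(axis=(3, 5, 7))
        return np.ascontiguousarray(y)

    def backward(self, dy):
        B, C, H, W, T = self._in_shape
        p0, p1, p2 = self.pool
        scale = 1.0 / (p0 * p1 * p2)
        dx = np.broadcast_to(
            (dy * scale)[:, :, :, None, :, None, :, None],
            (B, C, H // p0, p0, W // p1, p1, T // p2, p2))
        return np.ascontiguousarray(dx).reshape(self._in_shape)


class MaxPoolTime(Layer):
    """Non-overlapping max pooling over the last (time) axis."""

    def __init__(self, k: int = 2):
        self.k = k

    def forward(self, x, training=False):
        T = x.shape[-1]
        if T % self.k:
            raise ValueError(f"time extent {T} not divisible by pool {self.k}")
        xr = x.reshape(x.shape[:-1] + (T // self.k, self.k))
        self._arg = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dy):
        out = np.zeros(self._in_shape[:-1] + (self._in_shape[-1] // self.k, self.k),
                       dtype=dy.dtype)
        np.put_along_axis(out, self._arg[..., None], dy[..., None], axis=-1)
        return out.reshape(self._in_shape)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p <= 1.0:
            raise ValueError("dropout rate must be in [0, 1]")
        self.p, self.rng = p, rng

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if self.p >= 1.0:
            self._mask = np.zeros_like(x)
        else:
            keep = (self.rng.random(x.shape) >= self.p).astype(x.dtype)
            self._mask = keep / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class LSTM(Layer):
    """Single-layer batch-first LSTM: [B, S, F] -> [B, S, H]."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32, name="lstm"):
        self.hidden = hidden
        bound = 1.0 / np.sqrt(hidden)
        self.Wx = Parameter(_uniform(rng, (n_in, 4 * hidden), bound, dtype), f"{name}.Wx")
        self.Wh = Parameter(_uniform(rng, (hidden, 4 * hidden), bound, dtype), f"{name}.Wh")
        self.b = Parameter(np.zeros(4 * hidden, dtype=dtype), f"{name}.b")

    def params(self):
        return [self.Wx, self.Wh, self.b]

    @staticmethod
    def _sig(z):
        return 1.0 / (1.0 + np.exp(-z))

    def forward(self, x, training=False):
        B, S, F = x.shape
        Hn = self.hidden
        h = np.zeros((B, Hn), dtype=x.dtype)
        c = np.zeros((B, Hn), dtype=x.dtype)
        self._x = x
        self._cache = []
        out = np.empty((B, S, Hn), dtype=x.dtype)
        for s in range(S):
            z = x[:, s] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = self._sig(z[:, :Hn])
            f = self._sig(z[:, Hn:2 * Hn])
            g = np.tanh(z[:, 2 * Hn:3 * Hn])
            o = self._sig(z[:, 3 * Hn:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            out[:, s] = h
        self._out = out
        return out

    def backward(self, dy):
        B, S, F = self._x.shape
        Hn = self.hidden
        dx = np.zeros_like(self._x)
        dh_next = np.zeros((B, Hn), dtype=dy.dtype)
        dc_next = np.zeros((B, Hn), dtype=dy.dtype)
        for s in reversed(range(S)):
            h_prev, c_prev, i, f, g, o, tc = self._cache[s]
            dh = dy[:, s] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            self.Wx.grad += self._x[:, s].T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, s] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
            dc_next = dc * f
        return dx


class SelfAttention(Layer):
    """Single-head scaled dot-product self-attention over [B, S, d].

    Q, K, V are learned linear maps of the input; the similarity Q K^T is
    scaled by 1/sqrt(d) before the row softmax.
    """

    def __init__(self, d: int, rng: np.random.Generator, dtype=np.float32,
                 name="attn"):
        self.d = d
        bound = 1.0 / np.sqrt(d)
        self.Wq = Parameter(_uniform(rng, (d, d), bound, dtype), f"{name}.Wq")
        self.Wk = Parameter(_uniform(rng, (d, d), bound, dtype), f"{name}.Wk")
        self.Wv = Parameter(_uniform(rng, (d, d), bound, dtype), f"{name}.Wv")
        self.bq = Parameter(np.zeros(d, dtype=dtype), f"{name}.bq")
        self.bk = Parameter(np.zeros(d, dtype=dtype), f"{name}.bk")
        self.bv = Parameter(np.zeros(d, dtype=dtype), f"{name}.bv")

    def params(self):
        return [self.Wq, self.Wk, self.Wv, self.bq, self.bk, self.bv]

    def forward(self, x, training=False):
        if x.shape[-1] != self.d:
            raise ValueError(f"expected feature dim {self.d}, got {x.shape[-1]}")
        Q = x @ self.Wq.value + self.bq.value
        K = x @ self.Wk.value + self.bk.value
        V = x @ self.Wv.value + self.bv.value
        logits = Q @ K.transpose(0, 2, 1) / np.sqrt(self.d)
        logits -= logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        A = e / e.sum(axis=-1, keepdims=True)
        y = A @ V
        self._cache = (x, Q, K, V, A)
        return y

    @property
    def last_attention(self):
        return self._cache[4]

    def backward(self, dy):
        x, Q, K, V, A = self._cache
        dV = A.transpose(0, 2, 1) @ dy
        dA = dy @ V.transpose(0, 2, 1)
        dlog = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        scale = 1.0 / np.sqrt(self.d)
        dQ = dlog @ K * scale
        dK = dlog.transpose(0, 2, 1) @ Q * scale
        x2 = x.reshape(-1, self.d)
        for W, b, dM in ((self.Wq, self.bq, dQ), (self.Wk, self.bk, dK),
                         (self.Wv, self.bv, dV)):
            dM2 = dM.reshape(-1, self.d)
            W.grad += x2.T @ dM2
            b.grad += dM2.sum(axis=0)
        return (dQ @ self.Wq.value.T + dK @ self.Wk.value.T
                + dV @ self.Wv.value.T)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


# ---------------------------------------------------------------------------
# Losses and optimizer
# ---------------------------------------------------------------------------

def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    dp = p.copy()
    dp[np.arange(n), labels] -= 1.0
    return float(loss), (dp / n).astype(logits.dtype)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    return float(np.mean(diff ** 2)), (2.0 * diff / diff.size).astype(pred.dtype)


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
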