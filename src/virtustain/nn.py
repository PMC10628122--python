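"""Minimal convolutional-network framework used by the virtual-staining GAN.

Implements exactly what the pix2pix generator/discriminator pair needs —
strided 4x4 convolutions and transposed convolutions (im2col-based), batch
normalization, the usual activations, dropout, the Adam optimizer, and
spectral normalization by power iteration — as plain numpy with hand-written
backward passes.  Arrays are ``(N, C, H, W)`` float32; weights are
initialized from N(0, 0.02) as is conventional for this architecture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "Sigmoid",
    "Dropout",
    "Sequential",
    "Adam",
    "SpectralNormState",
    "spectral_normalize",
    "bce_with_logits",
]

WEIGHT_STD = 0.02
DTYPE = np.float32  # weights/activations; float64 costs 2x memory traffic


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


# ---------------------------------------------------------------------------
# im2col helpers


def _out_size(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def _im2col(x: np.ndarray, k: int, s: int, p: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::s, ::s, :, :]  # (N, C, Ho, Wo, k, k)
    ho, wo = win.shape[2], win.shape[3]
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)


def _col2im(cols: np.ndarray, xshape: tuple, k: int, s: int, p: int) -> np.ndarray:
    """Scatter-add inverse of :func:`_im2col`."""
    n, c, h, w = xshape
    ho, wo = _out_size(h, k, s, p), _out_size(w, k, s, p)
    g = cols.reshape(n, c, k, k, ho, wo)
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    for ki in range(k):
        for kj in range(k):
            xp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += g[:, :, ki, kj]
    return xp[:, :, p : p + h, p : p + w] if p else xp


# ---------------------------------------------------------------------------
# layers


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2, pad: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self.W = Param(WEIGHT_STD * rng.standard_normal((cout, cin * k * k), dtype=DTYPE), "conv.W")
        self.b = Param(np.zeros(cout, dtype=DTYPE), "conv.b")

    def _weight(self) -> np.ndarray:
        return self.W.value

    def _weight_backward(self, gW: np.ndarray) -> None:
        self.W.grad += gW

    def forward(self, x, train=True):
        self._xshape = x.shape
        self._cols = _im2col(x, self.k, self.stride, self.pad)
        n = x.shape[0]
        ho = _out_size(x.shape[2], self.k, self.stride, self.pad)
        wo = _out_size(x.shape[3], self.k, self.stride, self.pad)
        out = np.matmul(self._weight(), self._cols) + self.b.value[None, :, None]
        return out.reshape(n, self.cout, ho, wo)

    def backward(self, gout):
        n = gout.shape[0]
        gflat = gout.reshape(n, self.cout, -1)
        self._weight_backward(np.tensordot(gflat, self._cols, axes=([0, 2], [0, 2])))
        self.b.grad += gout.sum(axis=(0, 2, 3))
        gcols = np.matmul(self._weight().T, gflat)
        return _col2im(gcols, self._xshape, self.k, self.stride, self.pad)

    def params(self):
        return [self.W, self.b]


class ConvTranspose2d(Layer):
    """Stride-``s`` transposed convolution (output size ``s*(H-1) + k - 2p``)."""

    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2, pad: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self.W = Param(WEIGHT_STD * rng.standard_normal((cin, cout * k * k), dtype=DTYPE), "convT.W")
        self.b = Param(np.zeros(cout, dtype=DTYPE), "convT.b")

    def forward(self, x, train=True):
        n, _, h, w = x.shape
        self._x = x
        ho = self.stride * (h - 1) + self.k - 2 * self.pad
        wo = self.stride * (w - 1) + self.k - 2 * self.pad
        self._oshape = (n, self.cout, ho, wo)
        xf = x.reshape(n, self.cin, h * w)
        cols = np.matmul(self.W.value.T, xf)  # (N, cout*k*k, h*w)
        out = _col2im(cols, self._oshape, self.k, self.stride, self.pad)
        return out + self.b.value[None, :, None, None]

    def backward(self, gout):
        n = gout.shape[0]
        gcols = _im2col(gout, self.k, self.stride, self.pad)  # (N, cout*k*k, h*w)
        xf = self._x.reshape(n, self.cin, -1)
        self.W.grad += np.tensordot(xf, gcols, axes=([0, 2], [0, 2]))
        self.b.grad += gout.sum(axis=(0, 2, 3))
        gx = np.matmul(self.W.value, gcols)
        return gx.reshape(self._x.shape)

    def params(self):
        return [self.W, self.b]


class BatchNorm2d(Layer):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(c, dtype=DTYPE), "bn.gamma")
        self.beta = Param(np.zeros(c, dtype=DTYPE), "bn.beta")
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)

    def forward(self, x, train=True):
        self._count = x.shape[0] * x.shape[2] * x.shape[3]
        if train and self._count > 1:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        elif train:
            # single element per channel: normalization is degenerate; pass
            # through the affine part only
            self._xhat = np.zeros_like(x)
            self._istd = np.zeros(x.shape[1])
            return x * self.gamma.value[None, :, None, None] + self.beta.value[None, :, None, None]
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._istd[None, :, None, None]
        return self._xhat * self.gamma.value[None, :, None, None] + self.beta.value[None, :, None, None]

    def backward(self, gout):
        self.beta.grad += gout.sum(axis=(0, 2, 3))
        self.gamma.grad += (gout * self._xhat).sum(axis=(0, 2, 3))
        if self._count <= 1:
            return gout * self.gamma.value[None, :, None, None]
        m = self._count
        gxhat = gout * self.gamma.value[None, :, None, None]
        s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (gxhat * self._xhat).sum(axis=(0, 2, 3), keepdims=True)
        istd = self._istd[None, :, None, None]
        return istd / m * (m * gxhat - s1 - self._xhat * s2)

    def params(self):
        return [self.gamma, self.beta]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gout):
        return np.where(self._mask, gout, self.slope * gout)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(0.0)


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gout):
        return gout * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, gout):
        return gout * self._y * (1.0 - self._y)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x, train=True):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gout):
        return gout if self._mask is None else gout * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gout):
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


# ---------------------------------------------------------------------------
# spectral normalization


@dataclass
class SpectralNormState:
    """Persistent left/right power-iteration vectors for one weight matrix."""

    u: np.ndarray
    v: np.ndarray

    @classmethod
    def init(cls, shape_2d: tuple[int, int], rng: np.random.Generator) -> "SpectralNormState":
        u = rng.standard_normal(shape_2d[0])
        v = rng.standard_normal(shape_2d[1])
        return cls(u / np.linalg.norm(u), v / np.linalg.norm(v))


def spectral_normalize(
    W: np.ndarray,
    n_power_iterations: int = 1,
    state: SpectralNormState | None = None,
    rng: np.random.Generator | None = None,
    tol: float | None = None,
    max_iterations: int = 50,
) -> tuple[np.ndarray, float, SpectralNormState]:
    """Divide ``W`` by its spectral norm estimated with power iteration.

    ``W`` is reshaped to 2-D as ``(rows, -1)``.  Runs ``n_power_iterations``
    updates; with ``tol`` set, iteration continues (up to ``max_iterations``)
    until the sigma estimate is stable to that relative tolerance — with
    warm-started persistent vectors this typically costs only a few extra
    matrix-vector products and keeps the Lipschitz bound tight at every
    training step.  Returns the normalized weight (original shape), the
    spectral-norm estimate ``sigma``, and the updated persistent state.  A
    zero matrix is returned unchanged with a warning (its spectral norm is
    undefined for normalization purposes).
    """
    if n_power_iterations < 1:
        raise ValueError("n_power_iterations must be >= 1")
    W = np.asarray(W, dtype=float)
    W2 = W.reshape(W.shape[0], -1)
    if not np.any(W2):
        warnings.warn("spectral_normalize: zero matrix left unchanged")
        return W, 0.0, state or SpectralNormState.init(W2.shape, rng or np.random.default_rng())
    if state is None:
        state = SpectralNormState.init(W2.shape, rng or np.random.default_rng())
    u, v = state.u, state.v
    sigma_prev = None
    for it in range(max_iterations if tol is not None else n_power_iterations):
        v = W2.T @ u
        v /= np.linalg.norm(v) + 1e-12
        u = W2 @ v
        u /= np.linalg.norm(u) + 1e-12
        if tol is not None and it + 1 >= n_power_iterations:
            sigma_now = float(u @ W2 @ v)
            if sigma_prev is not None and abs(sigma_now - sigma_prev) <= tol * sigma_now:
                break
            sigma_prev = sigma_now
    sigma = float(u @ W2 @ v)
    state.u, state.v = u, v
    return W / sigma, sigma, state


class SpectralNormConv2d(Conv2d):
    """Conv2d whose effective weight is spectrally normalized at every
    forward pass (discriminator Lipschitz control).

    The spectral norm is computed exactly from the layer's (small) Gram
    matrix ``W W^T`` rather than by warm-started power iteration: random
    convolution weights have a quasi-degenerate top of the singular
    spectrum, where power iteration converges too slowly to keep a certified
    Lipschitz bound while the weights move.  The rows of the reshaped weight
    never exceed the filter count, so the exact computation costs one
    ``(rows x rows)`` eigendecomposition per forward.  The free-standing
    :func:`spectral_normalize` remains the classical power-iteration
    estimator.
    """

    def __init__(self, *args, n_power_iterations: int = 1,
                 rng: np.random.Generator | None = None, **kwargs):
        super().__init__(*args, rng=rng, **kwargs)
        self.n_power_iterations = n_power_iterations
        self.sn_state = SpectralNormState.init(
            (self.W.value.shape[0], self.W.value.reshape(self.W.value.shape[0], -1).shape[1]),
            rng or np.random.default_rng(),
        )
        self._sigma = 1.0

    def _weight(self):
        W2 = self.W.value.reshape(self.W.value.shape[0], -1).astype(np.float64)
        if not np.any(W2):
            warnings.warn("spectral norm of zero weight undefined; left unchanged")
            self._W_bar = self.W.value
            self._sigma = 1.0
            return self._W_bar
        G = W2 @ W2.T
        lam, vec = np.linalg.eigh(G)
        sigma = float(np.sqrt(max(lam[-1], 0.0)))
        u = vec[:, -1]
        v = W2.T @ u / (sigma + 1e-12)
        self.sn_state.u, self.sn_state.v = u, v
        self._sigma = sigma
        self._W_bar = (W2 / sigma).astype(DTYPE)
        return self._W_bar

    def _weight_backward(self, gWbar):
        # d(W/sigma)/dW with sigma = u^T W v (u, v treated as constants):
        # grad_W = (grad_Wbar - <grad_Wbar, W_bar> u v^T) / sigma
        u, v = self.sn_state.u, self.sn_state.v
        inner = float(np.sum(gWbar * self._W_bar))
        self.W.grad += (gWbar - inner * np.outer(u, v)) / self._sigma

    def normalized_weight(self) -> np.ndarray:
        """Current effective (normalized) weight matrix, 2-D."""
        return self._weight().reshape(self.W.value.shape[0], -1)


# ---------------------------------------------------------------------------
# optimizer and losses


try:  # fused single-pass update; the optimizer is memory-bound in pure numpy
    from numba import njit

    @njit(fastmath=True)
    def _adam_kernel(p, g, m, v, b1, b2, lr_t, eps_t):  # pragma: no cover
        for i in range(p.size):
            mi = b1 * m[i] + (1.0 - b1) * g[i]
            vi = b2 * v[i] + (1.0 - b2) * g[i] * g[i]
            m[i] = mi
            v[i] = vi
            p[i] -= lr_t * mi / (np.sqrt(vi) + eps_t)

except ImportError:  # pragma: no cover
    _adam_kernel = None


class Adam:
    def __init__(self, params: list[Param], lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        # fold both bias corrections into a per-step scalar learning rate
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        eps_t = self.eps * np.sqrt(1 - b2**self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if _adam_kernel is not None:
                _adam_kernel(p.value.ravel(), g.ravel(), m.ravel(), v.ravel(),
                             np.float32(b1), np.float32(b2),
                             np.float32(lr_t), np.float32(eps_t))
                continue
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            upd = np.sqrt(v)
            upd += eps_t
            np.divide(m, upd, out=upd)
            upd *= lr_t
            p.value -= upd

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def bce_with_logits(z: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy on logits against a constant
    target (0 or 1); returns (mean loss, gradient w.r.t. z)."""
    loss = np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z)))
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    return float(loss.mean()), (p - target) / z.size
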