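"""Minimal CPU neural-network engine (float32, NCHW) backing the axis classifiers.

Implements exactly the layer vocabulary the classifiers need: 3x3 "same"
convolution, per-channel batch normalization, ReLU, 2x2/stride-2 max
pooling, a dense head and softmax cross-entropy, trained with SGD with
momentum.  Convolutions run as one BLAS GEMM per image over an im2col
buffer laid out channels-first, so every fill is a long contiguous memcpy
and every GEMM writes its output exactly once — fresh large allocations
and short copy runs are the dominant costs on this target, so workspaces
are cached and reused.  Large batches are processed in
gradient-accumulating micro-batches to bound activation memory.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3x3",
    "BatchNorm",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "Sequential",
    "softmax",
    "weighted_xent_grad",
    "sgdm_step",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_xent_grad(
    logits: np.ndarray, labels: np.ndarray, weights: np.ndarray, norm: float
) -> tuple[float, np.ndarray]:
    """Weighted softmax cross-entropy; returns (summed loss, dlogits).

    ``norm`` is the total sample weight of the enclosing minibatch so that
    micro-batch gradients accumulate to the exact minibatch gradient.
    """
    p = softmax(logits)
    n = logits.shape[0]
    w = weights[labels]
    loss = float(-(w * np.log(p[np.arange(n), labels] + 1e-12)).sum() / norm)
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    d *= (w / norm)[:, None]
    return loss, d.astype(np.float32)


class _Param:
    __slots__ = ("value", "grad", "vel")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.vel = np.zeros_like(self.value)


class Layer:
    params: dict[str, _Param]

    def __init__(self):
        self.params = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _Workspace:
    """Cached (padded image, im2col matrix) buffer pairs keyed by geometry."""

    def __init__(self):
        self._bufs: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}

    def get(self, c: int, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
        key = (c, h, w)
        if key not in self._bufs:
            xp = np.zeros((c, h + 2, w + 2), np.float32)
            col = np.zeros((9 * c, h * w), np.float32)
            self._bufs[key] = (xp, col)
        return self._bufs[key]


def _fill_col(xp: np.ndarray, col: np.ndarray, h: int, w: int) -> None:
    """col[(k*c + cc), :] = channel cc of xp shifted by offset k.

    Each assignment copies rows of ``w`` contiguous floats.
    """
    c = xp.shape[0]
    col4 = col.reshape(9, c, h, w)
    k = 0
    for dy in range(3):
        for dx in range(3):
            col4[k] = xp[:, dy : dy + h, dx : dx + w]
            k += 1


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero "same" padding, channels-first.

    Weights are stored as (9*c_in, c_out), offset-major; the forward pass
    for one image is the single GEMM  W.T @ col  with col of shape
    (9*c_in, H*W).
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, first: bool = False):
        super().__init__()
        std = np.sqrt(2.0 / (9 * c_in))
        self.params["W"] = _Param(rng.normal(0.0, std, size=(9 * c_in, c_out)))
        self.params["b"] = _Param(np.zeros(c_out))
        self.c_in, self.c_out = c_in, c_out
        self.first = first  # first layer skips dx computation
        self._ws_f = _Workspace()
        self._ws_b = _Workspace()
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        out = np.empty((n, self.c_out, h, w), np.float32)
        WT = self.params["W"].value.T  # (c_out, 9*c_in); F-contiguous view
        for i in range(n):
            xp, col = self._ws_f.get(c, h, w)
            xp[:, 1:-1, 1:-1] = x[i]
            _fill_col(xp, col, h, w)
            np.matmul(WT, col, out=out[i].reshape(self.c_out, h * w))
        out += self.params["b"].value[:, None, None]
        if train:
            self._x = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        x = self._x
        n, c, h, w = x.shape
        W = self.params["W"].value
        need_dx = not self.first
        dx = np.empty_like(x) if need_dx else None
        if need_dx:
            # transposed convolution: flip offsets, swap channel roles
            Wb = np.ascontiguousarray(
                W.reshape(9, self.c_in, self.c_out)[::-1].transpose(1, 0, 2)
            ).reshape(self.c_in, 9 * self.c_out)
        dW, db = self.params["W"].grad, self.params["b"].grad
        for i in range(n):
            xp, col = self._ws_f.get(c, h, w)
            xp[:, 1:-1, 1:-1] = x[i]
            _fill_col(xp, col, h, w)
            d2 = dout[i].reshape(self.c_out, h * w)
            dW += col @ d2.T
            db += d2.sum(axis=1)
            if need_dx:
                gp, gcol = self._ws_b.get(self.c_out, h, w)
                gp[:, 1:-1, 1:-1] = dout[i]
                _fill_col(gp, gcol, h, w)
                np.matmul(Wb, gcol, out=dx[i].reshape(self.c_in, h * w))
        self._x = None
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W) with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = _Param(np.ones(c))
        self.params["beta"] = _Param(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)
        self._warm = False
        self._cache = None

    @staticmethod
    def _stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # single-pass per-channel mean / variance; activations are O(1)
        # so the E[x^2] - E[x]^2 form is numerically safe
        m = float(x.shape[0] * x.shape[2] * x.shape[3])
        s1 = x.sum(axis=(0, 2, 3), dtype=np.float64)
        s2 = np.einsum("ncij,ncij->c", x, x, dtype=np.float64)
        mean = s1 / m
        var = np.maximum(s2 / m - mean**2, 0.0)
        return mean.astype(np.float32), var.astype(np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        g = self.params["gamma"].value
        b = self.params["beta"].value
        if not train:
            # fused affine: y = A*x + B with frozen statistics
            invstd = 1.0 / np.sqrt(self.running_var + self.eps)
            a = (g * invstd).astype(np.float32)
            bias = (b - g * invstd * self.running_mean).astype(np.float32)
            out = x * a[:, None, None]
            out += bias[:, None, None]
            return out
        mean, var = self._stats(x)
        if not self._warm:
            self.running_mean[:] = mean
            self.running_var[:] = var
            self._warm = True
        else:
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = x - mean[:, None, None]
        xhat *= invstd[:, None, None]
        self._cache = (xhat, invstd)
        out = xhat * g[:, None, None]
        out += b[:, None, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        # mutates dout in place (every upstream gradient is a fresh array)
        xhat, invstd = self._cache
        g = self.params["gamma"].value
        m = float(dout.shape[0] * dout.shape[2] * dout.shape[3])
        dgamma = np.einsum("ncij,ncij->c", dout, xhat, dtype=np.float64).astype(np.float32)
        dbeta = dout.sum(axis=(0, 2, 3), dtype=np.float64).astype(np.float32)
        self.params["gamma"].grad += dgamma
        self.params["beta"].grad += dbeta
        dout *= m
        dout -= dbeta[:, None, None]
        xhat *= dgamma[:, None, None]
        dout -= xhat
        dout *= (g * invstd / m)[:, None, None]
        self._cache = None
        return dout


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        # mutates dout in place (upstream gradients are fresh arrays)
        np.multiply(dout, self._mask, out=dout)
        self._mask = None
        return dout


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; trailing odd rows/columns are dropped.

    Backward splits the gradient equally among tied window maxima (a valid
    subgradient; ties are measure-zero for continuous activations).
    """

    def __init__(self):
        super().__init__()
        self._cache = None

    @staticmethod
    def _windows(x: np.ndarray):
        h2, w2 = x.shape[2] // 2, x.shape[3] // 2
        return (
            x[:, :, 0 : h2 * 2 : 2, 0 : w2 * 2 : 2],
            x[:, :, 0 : h2 * 2 : 2, 1 : w2 * 2 : 2],
            x[:, :, 1 : h2 * 2 : 2, 0 : w2 * 2 : 2],
            x[:, :, 1 : h2 * 2 : 2, 1 : w2 * 2 : 2],
        )

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        w00, w01, w10, w11 = self._windows(x)
        out = np.maximum(np.maximum(w00, w01), np.maximum(w10, w11))
        if train:
            self._cache = (x, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, out = self._cache
        wins = self._windows(x)
        masks = [w == out for w in wins]
        count = masks[0].astype(np.float32)
        for mk in masks[1:]:
            count += mk
        share = dout / count
        dx = np.zeros_like(x)
        for dwin, mk in zip(self._windows(dx), masks):
            dwin += np.where(mk, share, 0.0)
        self._cache = None
        return dx


class Flatten(Layer):
    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / d_in)
        self.params["W"] = _Param(rng.normal(0.0, std, size=(d_in, d_out)))
        self.params["b"] = _Param(np.zeros(d_out))
        self._x = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["W"].value + self.params["b"].value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.params["W"].grad += self._x.T @ dout
        self.params["b"].grad += dout.sum(axis=0)
        dx = dout @ self.params["W"].value.T
        self._x = None
        return dx


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
            if dout is None:
                break

    def parameters(self) -> list[_Param]:
        return [p for layer in self.layers for p in layer.params.values()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_params(self) -> int:
        return sum(p.value.size for p in self.parameters())


def sgdm_step(net: Sequential, lr: float, momentum: float) -> None:
    """Classic SGD-with-momentum update: v <- mu*v - lr*g; p <- p + v."""
    for p in net.parameters():
        p.vel *= momentum
        p.vel -= lr * p.grad
        p.value += p.vel
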