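"""Minimal numpy neural-network engine.

Self-contained layers (convolution via im2col + BLAS, strided and transposed
convolutions, batch normalization, fully connected layers) with explicit
forward/backward passes and an Adam optimizer.  Everything is float32 and
deterministic for a fixed `numpy.random.Generator`.

Conventions
-----------
* Activations are NCHW: ``(batch, channels, rows, cols)``.
* Each layer owns its parameters and gradients in two parallel dicts,
  ``params`` and ``grads``; :func:`collect_params` flattens a named layer
  tree into ``{"prefix/param": array}`` suitable for checkpointing.
* ``forward(x, train=...)`` caches whatever ``backward(dy)`` needs; a layer
  instance therefore processes one batch at a time.
"""

from __future__ import annotations

import numpy as np

from . import nn_kernels as kernels

F32 = np.float32


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


class Layer:
    """Base class: parameter-less identity.

    ``in_scale`` is a fixed (non-learned) divisor applied to the layer
    input; calibration routines use it to standardize inputs whose scale
    the surrounding architecture cannot control, without shrinking the
    weights themselves (Adam plus L2 treats small weights badly).
    """

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.in_scale: float = 1.0

    def _scale_in(self, x):
        s = getattr(self, "in_scale", 1.0)
        return x if s == 1.0 else (x / F32(s))

    def _scale_back(self, dx):
        s = getattr(self, "in_scale", 1.0)
        return dx if s == 1.0 else (dx / F32(s))

    def forward(self, x, train=False):
        return x

    def backward(self, dy):
        return dy

    def zero_grad(self):
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with square kernel, NCHW.

    Three execution paths chosen by shape: a plain matmul for 1x1 kernels,
    numba direct loops for stride-1 kernels (the dominant cost at this
    model's small channel counts), and channels-last im2col + GEMM for
    strided kernels and as the no-numba fallback.
    """

    def __init__(self, rng, cin, cout, k, stride=1, pad=0, bias=True):
        super().__init__()
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self.params["W"] = he_init(rng, (cout, cin, k, k), cin * k * k)
        self.grads["W"] = np.zeros_like(self.params["W"])
        if bias:
            self.params["b"] = np.zeros(cout, dtype=F32)
            self.grads["b"] = np.zeros(cout, dtype=F32)

    def _bias(self):
        return self.params.get("b", np.zeros(self.cout, dtype=F32))

    # --- 1x1: channel mixing is a single GEMM
    def _forward_1x1(self, x):
        self._x = x
        y = np.tensordot(x, self.params["W"][:, :, 0, 0], axes=([1], [1]))
        y += self._bias()
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def _backward_1x1(self, dy):
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 3, 1))
        self.grads["W"][:, :, 0, 0] += np.tensordot(
            dyt, self._x, axes=([0, 1, 2], [0, 2, 3]))
        if "b" in self.grads:
            self.grads["b"] += dyt.sum(axis=(0, 1, 2))
        dx = np.tensordot(dyt, self.params["W"][:, :, 0, 0], axes=([3], [0]))
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))

    # --- stride 1, k > 1: numba direct loops on the padded input
    def _forward_direct(self, x):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else \
            np.ascontiguousarray(x)
        self._xp = xp
        return kernels.conv2d_fwd(xp, self.params["W"], self._bias())

    def _backward_direct(self, dy):
        p = self.pad
        dy = np.ascontiguousarray(dy)
        dW, db = kernels.conv2d_bwd_dw(dy, self._xp, self.k)
        self.grads["W"] += dW
        if "b" in self.grads:
            self.grads["b"] += db
        dxp = kernels.conv2d_bwd_dx(dy, self.params["W"],
                                    self._xp.shape[2], self._xp.shape[3])
        return dxp[:, :, p:-p, p:-p] if p else dxp

    # --- generic: channels-last im2col + GEMM
    def _weight_mat(self):
        # rows ordered (ki, kj, cin) to match the packed column layout
        return np.ascontiguousarray(
            self.params["W"].transpose(2, 3, 1, 0).reshape(-1, self.cout))

    def _forward_im2col(self, x):
        k, s, p = self.k, self.stride, self.pad
        n, c = x.shape[0], x.shape[1]
        xt = np.ascontiguousarray(x.transpose(0, 2, 3, 1))
        if p:
            xt = np.pad(xt, ((0, 0), (p, p), (p, p), (0, 0)))
        ho = (xt.shape[1] - k) // s + 1
        wo = (xt.shape[2] - k) // s + 1
        cols = np.empty((n, ho, wo, k * k * c), dtype=F32)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            cols[..., idx * c:(idx + 1) * c] = xt[:, i:i + s * ho:s, j:j + s * wo:s, :]
        cols = cols.reshape(-1, k * k * c)
        y = cols @ self._weight_mat()
        if "b" in self.params:
            y += self.params["b"]
        self._cache = (cols, xt.shape, ho, wo)
        return np.ascontiguousarray(
            y.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2))

    def _backward_im2col(self, dy):
        cols, xtshape, ho, wo = self._cache
        n, c = xtshape[0], xtshape[3]
        k, s, p = self.k, self.stride, self.pad
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        dWm = cols.T @ dyf  # (k*k*c, cout)
        self.grads["W"] += dWm.reshape(k, k, c, self.cout).transpose(3, 2, 0, 1)
        if "b" in self.grads:
            self.grads["b"] += dyf.sum(axis=0)
        dcols = (dyf @ self._weight_mat().T).reshape(n, ho, wo, k * k * c)
        dxt = np.zeros(xtshape, dtype=F32)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            dxt[:, i:i + s * ho:s, j:j + s * wo:s, :] += \
                dcols[..., idx * c:(idx + 1) * c]
        if p:
            dxt = dxt[:, p:-p, p:-p, :]
        return np.ascontiguousarray(dxt.transpose(0, 3, 1, 2))

    def _path(self):
        if self.k == 1 and self.stride == 1:
            return "1x1"
        if self.stride == 1 and kernels.HAVE_NUMBA:
            return "direct"
        return "im2col"

    def forward(self, x, train=False):
        x = np.ascontiguousarray(self._scale_in(x), dtype=F32)
        path = self._path()
        if path == "1x1":
            return self._forward_1x1(x)
        if path == "direct":
            return self._forward_direct(x)
        return self._forward_im2col(x)

    def backward(self, dy):
        path = self._path()
        if path == "1x1":
            dx = self._backward_1x1(dy)
        elif path == "direct":
            dx = self._backward_direct(dy)
        else:
            dx = self._backward_im2col(dy)
        return self._scale_back(dx)


class ConvTranspose2d(Layer):
    """Transposed convolution with kernel == stride (non-overlapping tiles).

    Doubles (for k=2) the spatial resolution; used for the coarse-to-fine
    projections of the feedback pathway.
    """

    def __init__(self, rng, cin, cout, k=2):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.params["W"] = he_init(rng, (cin, cout, k, k), cin)
        self.params["b"] = np.zeros(cout, dtype=F32)
        self.grads["W"] = np.zeros_like(self.params["W"])
        self.grads["b"] = np.zeros(cout, dtype=F32)

    def forward(self, x, train=False):
        x = self._scale_in(x)
        n, c, h, w = x.shape
        k = self.k
        self._x = x
        y = np.einsum("nchw,cokl->nohkwl", x, self.params["W"], optimize=True)
        y = y.reshape(n, self.cout, h * k, w * k)
        y += self.params["b"][None, :, None, None]
        return y

    def backward(self, dy):
        n, co, H, W = dy.shape
        k = self.k
        dyt = dy.reshape(n, co, H // k, k, W // k, k)
        self.grads["W"] += np.einsum("nohkwl,nchw->cokl", dyt, self._x, optimize=True)
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        dx = np.einsum("nohkwl,cokl->nchw", dyt, self.params["W"], optimize=True)
        return self._scale_back(dx)


class Broadcast2d(Layer):
    """Transposed convolution from a 1x1 spatial input to a kxk map.

    Equivalent to a fully connected layer whose output is reshaped to
    ``(cout, k, k)``; expands the class-level feedback vector into a coarse
    spatial map.
    """

    def __init__(self, rng, cin, cout, k):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.params["W"] = he_init(rng, (cin, cout, k, k), cin)
        self.params["b"] = np.zeros(cout, dtype=F32)
        self.grads["W"] = np.zeros_like(self.params["W"])
        self.grads["b"] = np.zeros(cout, dtype=F32)

    def forward(self, x, train=False):  # x: (n, cin)
        x = self._scale_in(x)
        self._x = x
        y = np.einsum("nc,cokl->nokl", x, self.params["W"], optimize=True)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy):
        self.grads["W"] += np.einsum("nokl,nc->cokl", dy, self._x, optimize=True)
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        dx = np.einsum("nokl,cokl->nc", dy, self.params["W"], optimize=True)
        return self._scale_back(dx)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    Running statistics start at mean 0 / variance 1 so an untrained network
    in eval mode applies an (affine) identity.
    """

    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.c, self.momentum, self.eps = c, momentum, eps
        self.params["gamma"] = np.ones(c, dtype=F32)
        self.params["beta"] = np.zeros(c, dtype=F32)
        self.grads["gamma"] = np.zeros(c, dtype=F32)
        self.grads["beta"] = np.zeros(c, dtype=F32)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(F32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        self._cache = (xhat, ivar.astype(F32), train)
        return (
            self.params["gamma"][None, :, None, None] * xhat
            + self.params["beta"][None, :, None, None]
        )

    def backward(self, dy):
        xhat, ivar, train = self._cache
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        if not train:
            return dy * g * ivar[None, :, None, None]
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        return (
            ivar[None, :, None, None]
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            )
        ).astype(F32)


class Linear(Layer):
    def __init__(self, rng, fin, fout):
        super().__init__()
        self.params["W"] = he_init(rng, (fout, fin), fin)
        self.params["b"] = np.zeros(fout, dtype=F32)
        self.grads["W"] = np.zeros_like(self.params["W"])
        self.grads["b"] = np.zeros(fout, dtype=F32)

    def forward(self, x, train=False):
        x = self._scale_in(x)
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy):
        self.grads["W"] += dy.T @ self._x
        self.grads["b"] += dy.sum(axis=0)
        return self._scale_back(dy @ self.params["W"])


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class ResBlock(Layer):
    """conv(3x3) -> batch norm, added to a skip branch, then rectified.

    The skip branch is the identity when channel counts match and a 1x1
    convolution otherwise.  The trailing ReLU guarantees non-negative
    activities, which the modulatory feedback equation requires.
    """

    def __init__(self, rng, cin, cout, k=3):
        super().__init__()
        self.conv = Conv2d(rng, cin, cout, k, pad=k // 2)
        self.bn = BatchNorm2d(cout)
        self.proj = Conv2d(rng, cin, cout, 1, bias=False) if cin != cout else None
        self.children = {"conv": self.conv, "bn": self.bn}
        if self.proj is not None:
            self.children["proj"] = self.proj

    def forward(self, x, train=False):
        h = self.bn.forward(self.conv.forward(x, train), train)
        s = x if self.proj is None else self.proj.forward(x, train)
        y = h + s
        self._mask = y > 0
        return y * self._mask

    def backward(self, dy):
        dy = dy * self._mask
        dx = self.bn.backward(dy)
        dx = self.conv.backward(dx)
        if self.proj is None:
            dx = dx + dy
        else:
            dx = dx + self.proj.backward(dy)
        return dx


class DownBlock(Layer):
    """Strided 2x2 convolution halving the resolution, with BN + ReLU."""

    def __init__(self, rng, cin, cout):
        super().__init__()
        self.conv = Conv2d(rng, cin, cout, 2, stride=2)
        self.bn = BatchNorm2d(cout)
        self.children = {"conv": self.conv, "bn": self.bn}

    def forward(self, x, train=False):
        y = self.bn.forward(self.conv.forward(x, train), train)
        self._mask = y > 0
        return y * self._mask

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(dy * self._mask))


def iter_layers(layer):
    """Yield (suffix, leaf layer) pairs for a layer and its descendants."""
    kids = getattr(layer, "children", None)
    if not kids:
        yield "", layer
        return
    for name, child in kids.items():
        for suffix, leaf in iter_layers(child):
            yield (name if not suffix else f"{name}/{suffix}", leaf)


def collect_params(named_layers: dict[str, Layer]):
    """Flatten ``{prefix: layer}`` into ``(params, grads)`` name->array dicts."""
    params, grads = {}, {}
    for prefix, layer in named_layers.items():
        for suffix, leaf in iter_layers(layer):
            base = prefix if not suffix else f"{prefix}/{suffix}"
            for k, v in leaf.params.items():
                params[f"{base}/{k}"] = v
                grads[f"{base}/{k}"] = leaf.grads[k]
    return params, grads


def sigmoid(x):
    out = np.empty_like(x, dtype=F32)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam with decoupled-from-nothing L2 (weight decay added to the
    gradient, matching the classic formulation)."""

    def __init__(self, params: dict[str, np.ndarray], lr=1e-3, weight_decay=0.0,
                 betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            if self.wd:
                g = g + self.wd * p
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p -= (self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)).astype(p.dtype)
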