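"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough tensor machinery for a dense-block encoder–decoder network on
CPU: elementwise arithmetic, matmul, 2-D convolution (NHWC layout), batch
normalization, 2x2 max pooling, 2x bilinear/nearest upsampling, channel
concatenation and reductions. Gradients are accumulated by topological
traversal of the operation tape; every op's backward rule is exercised by
finite-difference checks in the test suite.

All data is float32. Tensors are NHWC: (batch, height, width, channels).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "relu",
    "sigmoid",
    "log",
    "clip",
    "matmul",
    "conv2d",
    "batchnorm",
    "maxpool2x2",
    "upsample2x",
    "concat",
    "tsum",
    "tmean",
    "reshape",
    "bce_with_logits",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over dimensions that were broadcast from `shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.shape))
            out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.shape))
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(
                        -g * self.data / (other.data ** 2), other.shape))
            out._backward = bwd
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    return out


# -- elementwise nonlinearities --------------------------------------------


def relu(x: Tensor) -> Tensor:
    out = _make(np.maximum(x.data, 0.0), (x,))
    if out.requires_grad:
        mask = x.data > 0

        def bwd(g):
            x._accumulate(g * mask)
        out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = _make(s, (x,))
    if out.requires_grad:
        def bwd(g):
            x._accumulate(g * s * (1.0 - s))
        out._backward = bwd
    return out


def log(x: Tensor) -> Tensor:
    out = _make(np.log(x.data), (x,))
    if out.requires_grad:
        def bwd(g):
            x._accumulate(g / x.data)
        out._backward = bwd
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    out = _make(np.clip(x.data, lo, hi), (x,))
    if out.requires_grad:
        mask = (x.data > lo) & (x.data < hi)

        def bwd(g):
            x._accumulate(g * mask)
        out._backward = bwd
    return out


# -- linear algebra ---------------------------------------------------------


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = _make(a.data @ b.data, (a, b))
    if out.requires_grad:
        def bwd(g):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)
        out._backward = bwd
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padding stride-1 convolution (cross-correlation), NHWC.

    `w` has shape (kh, kw, c_in, c_out) with kh, kw odd. Implemented as a
    sum of shifted GEMMs, one per kernel tap, so both directions reduce to
    BLAS calls.
    """
    n, h, wd, cin = x.shape
    kh, kw, cin_w, cout = w.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: {cin} vs {cin_w}")
    ph, pw = kh // 2, kw // 2

    if kh == 1 and kw == 1:  # pointwise: a single GEMM, no padding
        xr = x.data.reshape(-1, cin)
        wr = w.data.reshape(cin, cout)
        out_data = (xr @ wr).reshape(n, h, wd, cout)
        if b is not None:
            out_data += b.data
        out = _make(out_data, (x, w) if b is None else (x, w, b))
        if out.requires_grad:
            def bwd1(g):
                g2 = g.reshape(-1, cout)
                if w.requires_grad:
                    w._accumulate((xr.T @ g2).reshape(w.shape))
                if b is not None and b.requires_grad:
                    b._accumulate(g2.sum(axis=0))
                if x.requires_grad:
                    x._accumulate((g2 @ wr.T).reshape(x.shape))
            out._backward = bwd1
        return out

    # general k x k: sum of shifted GEMMs, one per kernel tap (faster than
    # im2col here: the unrolled-column copy is memory-bound on one core)
    xp = np.zeros((n, h + 2 * ph, wd + 2 * pw, cin), dtype=np.float32)
    xp[:, ph:ph + h, pw:pw + wd, :] = x.data
    out_data = np.zeros((n, h, wd, cout), dtype=np.float32)
    flat = out_data.reshape(-1, cout)
    for di in range(kh):
        for dj in range(kw):
            seg = xp[:, di:di + h, dj:dj + wd, :].reshape(-1, cin)
            flat += seg @ w.data[di, dj]
    if b is not None:
        out_data += b.data
    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents)
    if out.requires_grad:
        def bwd(g):
            g2 = g.reshape(-1, cout)
            if w.requires_grad:
                gw = np.empty_like(w.data)
                for di in range(kh):
                    for dj in range(kw):
                        seg = xp[:, di:di + h, dj:dj + wd, :].reshape(-1, cin)
                        gw[di, dj] = seg.T @ g2
                w._accumulate(gw)
            if b is not None and b.requires_grad:
                b._accumulate(g2.sum(axis=0))
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for di in range(kh):
                    for dj in range(kw):
                        gxp[:, di:di + h, dj:dj + wd, :] += (
                            g2 @ w.data[di, dj].T).reshape(n, h, wd, cin)
                x._accumulate(gxp[:, ph:ph + h, pw:pw + wd, :])
        out._backward = bwd
    return out


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, *, training: bool,
              running_mean: np.ndarray, running_var: np.ndarray,
              momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, H, W); NHWC input.

    In training mode the running statistics are updated in place.
    """
    axes = tuple(range(x.ndim - 1))
    c = x.shape[-1]
    if training:
        xr = x.data.reshape(-1, c)
        m = xr.shape[0]
        mu = xr.mean(axis=0)
        # single-pass variance: E[x^2] - mu^2 (float64 accumulator)
        var = (np.einsum("ij,ij->j", xr, xr, dtype=np.float64) / m
               - mu.astype(np.float64) ** 2).astype(np.float32)
        np.maximum(var, 0.0, out=var)
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = x.data - mu
    xhat *= inv_std
    out = _make(gamma.data * xhat + beta.data, (x, gamma, beta))
    if out.requires_grad:
        m = x.data.size // x.shape[-1]

        def bwd(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes))
            if x.requires_grad:
                if training:
                    gxh = g * gamma.data
                    gx = inv_std * (gxh - gxh.mean(axis=axes)
                                    - xhat * (gxh * xhat).sum(axis=axes) / m)
                else:
                    gx = g * gamma.data * inv_std
                x._accumulate(gx.astype(np.float32))
        out._backward = bwd
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    n, h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 needs even spatial dimensions")
    xt = (x.data.reshape(n, h // 2, 2, w // 2, 2, c)
          .transpose(0, 1, 3, 5, 2, 4)
          .reshape(n, h // 2, w // 2, c, 4))
    idx = xt.argmax(axis=-1)
    out_data = np.take_along_axis(xt, idx[..., None], axis=-1)[..., 0]
    out = _make(out_data, (x,))
    if out.requires_grad:
        def bwd(g):
            gx = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
            np.put_along_axis(gx, idx[..., None], g[..., None], axis=-1)
            gx = (gx.reshape(n, h // 2, w // 2, c, 2, 2)
                  .transpose(0, 1, 4, 2, 5, 3)
                  .reshape(n, h, w, c))
            x._accumulate(gx)
        out._backward = bwd
    return out


def _up1d(a: np.ndarray, axis: int) -> np.ndarray:
    """Double length along `axis` with bilinear weights (half-pixel centers)."""
    a = np.moveaxis(a, axis, 0)
    left = np.concatenate([a[:1], a[:-1]], axis=0)
    right = np.concatenate([a[1:], a[-1:]], axis=0)
    even = 0.25 * left + 0.75 * a
    odd = 0.75 * a + 0.25 * right
    out = np.stack([even, odd], axis=1).reshape((-1,) + a.shape[1:])
    return np.moveaxis(out, 0, axis)


def _up1d_t(g: np.ndarray, axis: int) -> np.ndarray:
    """Transpose (adjoint) of `_up1d` along `axis`."""
    g = np.moveaxis(g, axis, 0)
    n2 = g.shape[0]
    gpairs = g.reshape((n2 // 2, 2) + g.shape[1:])
    ge, go = gpairs[:, 0], gpairs[:, 1]
    gx = 0.75 * ge + 0.75 * go
    # even[i] takes 0.25 from x[i-1] (clamped at i=0 to x[0])
    gx[:-1] += 0.25 * ge[1:]
    gx[0] += 0.25 * ge[0]
    # odd[i] takes 0.25 from x[i+1] (clamped at i=n-1 to x[n-1])
    gx[1:] += 0.25 * go[:-1]
    gx[-1] += 0.25 * go[-1]
    return np.moveaxis(gx, 0, axis)


def upsample2x(x: Tensor, mode: str = "bilinear") -> Tensor:
    """Double spatial dimensions of an NHWC tensor."""
    if mode not in ("bilinear", "nearest"):
        raise ValueError(f"unknown upsample mode {mode!r}")
    if mode == "nearest":
        out_data = x.data.repeat(2, axis=1).repeat(2, axis=2)
    else:
        out_data = _up1d(_up1d(x.data, 1), 2)
    out = _make(out_data.astype(np.float32), (x,))
    if out.requires_grad:
        def bwd(g):
            if mode == "nearest":
                n, h2, w2, c = g.shape
                gx = g.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))
            else:
                gx = _up1d_t(_up1d_t(g, 2), 1)
            x._accumulate(gx.astype(np.float32))
        out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = _make(np.concatenate([t.data for t in tensors], axis=axis),
                tuple(tensors))
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward = bwd
    return out


def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = _make(x.data.sum(axis=axis, keepdims=keepdims), (x,))
    if out.requires_grad:
        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            x._accumulate(np.broadcast_to(g, x.shape).astype(np.float32))
        out._backward = bwd
    return out


def tmean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = _make(x.data.mean(axis=axis, keepdims=keepdims), (x,))
    if out.requires_grad:
        scale = x.data.size / max(out.data.size, 1)

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            x._accumulate(
                (np.broadcast_to(g, x.shape) / scale).astype(np.float32))
        out._backward = bwd
    return out


def reshape(x: Tensor, shape) -> Tensor:
    out = _make(x.data.reshape(shape), (x,))
    if out.requires_grad:
        def bwd(g):
            x._accumulate(g.reshape(x.shape))
        out._backward = bwd
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    reduction: str = "mean") -> Tensor:
    """Numerically stable binary cross-entropy on raw logits.

    loss = max(z,0) - z*t + log(1 + exp(-|z|)); gradient sigmoid(z) - t.
    """
    z = logits.data
    t = np.asarray(targets, dtype=np.float32)
    if t.shape != z.shape:
        raise ValueError(f"shape mismatch: logits {z.shape} vs targets {t.shape}")
    loss = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if reduction == "mean":
        val, scale = loss.mean(), loss.size
    elif reduction == "sum":
        val, scale = loss.sum(), 1
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    out = _make(np.float32(val), (logits,))
    if out.requires_grad:
        def bwd(g):
            s = 1.0 / (1.0 + np.exp(-z))
            logits._accumulate((g * (s - t) / scale).astype(np.float32))
        out._backward = bwd
    return out
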