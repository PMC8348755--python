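"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the primitives the MBConv classification network needs:
broadcast add/multiply, matmul, reshape, 2D convolution and depthwise
convolution (im2col / scatter-matrix col2im), batch normalization, swish
and sigmoid activations, global average pooling, and softmax
cross-entropy. All data is float32; gradients are accumulated by a
topological backward pass. Correctness of every primitive is pinned by
numerical-gradient tests.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.parents: tuple[Tensor, ...] = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in self.parents
        )

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# Elementwise / linear primitives
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return Tensor(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return Tensor(out_data, (a, b), backward)


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    orig = a.data.shape

    def backward(g):
        _accum(a, g.reshape(orig))

    return Tensor(a.data.reshape(shape), (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accum(a, g * s * (1.0 - s))

    return Tensor(s, (a,), backward)


def swish(a: Tensor) -> Tensor:
    """x * sigmoid(x), the activation used throughout the MBConv network."""
    s = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * s

    def backward(g):
        _accum(a, g * (s + a.data * s * (1.0 - s)))

    return Tensor(out_data, (a,), backward)


def global_avg_pool(a: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    n, c, h, w = a.data.shape
    out_data = a.data.mean(axis=(2, 3))

    def backward(g):
        _accum(a, np.broadcast_to(g[:, :, None, None] / (h * w), a.data.shape))

    return Tensor(out_data, (a,), backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels; returns a scalar tensor."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    nll = -np.log(np.maximum(probs[np.arange(n), labels], 1e-12))
    out_data = nll.mean()

    def backward(g):
        d = probs.copy()
        d[np.arange(n), labels] -= 1.0
        _accum(logits, g * d / n)

    return Tensor(out_data, (logits,), backward)


# ---------------------------------------------------------------------------
# Convolution via im2col
# ---------------------------------------------------------------------------

_COL_CACHE: dict[tuple, tuple] = {}


def _im2col_plan(h, w, kh, kw, stride, pad):
    """Index plan mapping padded-input positions to column entries, plus the
    sparse scatter matrix used for col2im in the backward pass."""
    key = (h, w, kh, kw, stride, pad)
    plan = _COL_CACHE.get(key)
    if plan is not None:
        return plan
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError(
            f"kernel {kh}x{kw} stride {stride} does not fit a "
            f"{h}x{w} input with padding {pad}"
        )
    i0 = np.repeat(stride * np.arange(ho), wo)[:, None]  # (L, 1)
    j0 = np.tile(stride * np.arange(wo), ho)[:, None]
    di = np.repeat(np.arange(kh), kw)[None, :]  # (1, K)
    dj = np.tile(np.arange(kw), kh)[None, :]
    spat_idx = ((i0 + di) * wp + (j0 + dj)).astype(np.int64)  # (L, K)
    lk = spat_idx.size
    scatter = sp.csr_matrix(
        (np.ones(lk, dtype=np.float32),
         (spat_idx.ravel(), np.arange(lk))),
        shape=(hp * wp, lk),
    )
    plan = (spat_idx, scatter, hp, wp, ho, wo)
    _COL_CACHE[key] = plan
    return plan


def _pad_input(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


def _col2im(dcols_flat: np.ndarray, scatter, n, c, hp, wp, pad):
    """dcols_flat: (N*C, L*K) -> gradient w.r.t. unpadded input."""
    dxp = scatter.dot(dcols_flat.T).T.reshape(n, c, hp, wp)
    if pad:
        dxp = dxp[:, :, pad:hp - pad, pad:wp - pad]
    return np.ascontiguousarray(dxp)


def conv2d(x: Tensor, weight: Tensor, stride: int = 1,
           pad: int | None = None) -> Tensor:
    """Cross-correlation of (N,Cin,H,W) with (Cout,Cin,kh,kw), no bias."""
    n, cin, h, w = x.data.shape
    cout, cin_w, kh, kw = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"input has {cin} channels, weight expects {cin_w}")
    if pad is None:
        pad = kh // 2
    spat_idx, scatter, hp, wp, ho, wo = _im2col_plan(h, w, kh, kw, stride, pad)
    xp = _pad_input(x.data, pad).reshape(n, cin, hp * wp)
    cols = xp[:, :, spat_idx]  # (N, Cin, L, K)
    colsm = cols.transpose(0, 2, 1, 3).reshape(n * ho * wo, cin * kh * kw)
    wm = weight.data.reshape(cout, cin * kh * kw)
    out_data = (colsm @ wm.T).reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)

    def backward(g):
        gm = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        if weight.requires_grad:
            _accum(weight, (gm.T @ colsm).reshape(weight.data.shape))
        if x.requires_grad:
            dcolsm = gm @ wm  # (N*L, Cin*K)
            dcols = dcolsm.reshape(n, ho * wo, cin, kh * kw).transpose(0, 2, 1, 3)
            dflat = dcols.reshape(n * cin, -1)
            _accum(x, _col2im(dflat, scatter, n, cin, hp, wp, pad))

    return Tensor(np.ascontiguousarray(out_data), (x, weight), backward)


def depthwise_conv2d(x: Tensor, weight: Tensor, stride: int = 1,
                     pad: int | None = None) -> Tensor:
    """Depthwise cross-correlation: weight (C, 1, kh, kw), one filter per
    input channel."""
    n, c, h, w = x.data.shape
    c_w, one, kh, kw = weight.data.shape
    if c_w != c or one != 1:
        raise ValueError(
            f"depthwise weight must be ({c}, 1, kh, kw), got {weight.data.shape}"
        )
    if pad is None:
        pad = kh // 2
    spat_idx, scatter, hp, wp, ho, wo = _im2col_plan(h, w, kh, kw, stride, pad)
    xp = _pad_input(x.data, pad).reshape(n, c, hp * wp)
    cols = xp[:, :, spat_idx]  # (N, C, L, K)
    wk = weight.data.reshape(c, kh * kw)
    out_data = np.einsum("nclk,ck->ncl", cols, wk).reshape(n, c, ho, wo)

    def backward(g):
        gl = g.reshape(n, c, ho * wo)
        if weight.requires_grad:
            dw = np.einsum("nclk,ncl->ck", cols, gl)
            _accum(weight, dw.reshape(weight.data.shape))
        if x.requires_grad:
            dcols = np.einsum("ncl,ck->nclk", gl, wk)
            _accum(x, _col2im(dcols.reshape(n * c, -1), scatter, n, c, hp, wp,
                              pad))

    return Tensor(np.ascontiguousarray(out_data), (x, weight), backward)


# ---------------------------------------------------------------------------
# Batch normalization
# ---------------------------------------------------------------------------

def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-3,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    In training mode, batch statistics are used and the running statistics
    are updated in place; in inference mode the running statistics are
    used.
    """
    n, c, h, w = x.data.shape
    g4 = gamma.data.reshape(1, c, 1, 1)
    b4 = beta.data.reshape(1, c, 1, 1)
    if training:
        m = n * h * w
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))  # unbiased
        inv_std = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mean.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
        out_data = g4 * xhat + b4

        def backward(grad):
            _accum(gamma, (grad * xhat).sum(axis=(0, 2, 3)))
            _accum(beta, grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gxhat = grad * g4
                mean_g = gxhat.mean(axis=(0, 2, 3), keepdims=True)
                mean_gx = (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                dx = (gxhat - mean_g - xhat * mean_gx) * inv_std.reshape(
                    1, c, 1, 1
                )
                _accum(x, dx)

    else:
        inv_std = (1.0 / np.sqrt(running_var + eps)).reshape(1, c, 1, 1)
        xhat = (x.data - running_mean.reshape(1, c, 1, 1)) * inv_std
        out_data = g4 * xhat + b4

        def backward(grad):
            _accum(gamma, (grad * xhat).sum(axis=(0, 2, 3)))
            _accum(beta, grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                _accum(x, grad * g4 * inv_std)

    return Tensor(out_data.astype(np.float32), (x, gamma, beta), backward)
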