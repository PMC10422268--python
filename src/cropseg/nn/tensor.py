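"""Minimal reverse-mode automatic differentiation on NumPy arrays.

All image tensors use the NCHW layout and float32 storage.  The op set is
exactly what the segmentation network needs: broadcasting add/mul, matmul,
same-padded 2-D convolution, 2x2 max pooling, 2x nearest upsampling,
channel/spatial pooling reductions, batch normalization and a fused
softmax cross-entropy loss.
"""

from __future__ import annotations

import numpy as np

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo = []
        seen = set()
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
                if id(p) not in seen and p._backward is not None:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Convenience arithmetic -------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t: Tensor, g: np.ndarray):
    if t.requires_grad:
        t.grad = g if t.grad is None else t.grad + g


def _node(data, parents, backward_fn) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._backward is not None for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward_fn
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Reduce gradient g to the given (broadcast-source) shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# Elementwise / linear algebra
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        _accumulate(a, g @ b.data.T)
        _accumulate(b, a.data.T @ g)

    return _node(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0)

    def backward(g):
        _accumulate(x, g * mask)

    return _node(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    z = np.clip(x.data, -60.0, 60.0)
    s = 1.0 / (1.0 + np.exp(-z))

    def backward(g):
        _accumulate(x, g * s * (1.0 - s))

    return _node(s, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    orig = x.data.shape
    out_data = x.data.reshape(shape)

    def backward(g):
        _accumulate(x, g.reshape(orig))

    return _node(out_data, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accumulate(t, piece)

    return _node(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# Convolution / pooling / resampling (NCHW)
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: int, H: int, W: int) -> np.ndarray:
    """(N, C, H+2p, W+2p) padded input -> (N*H*W, C*k*k) patch matrix."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(-1, xp.shape[1] * k * k)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 convolution; w has shape (Cout, Cin, k, k)."""
    N, C, H, W = x.data.shape
    Cout, Cin, k, _ = w.data.shape
    if Cin != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, kernel {Cin}")
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = _im2col(xp, k, H, W)
    wmat = w.data.reshape(Cout, -1)
    out = cols @ wmat.T
    if b is not None:
        out += b.data
    out_data = out.reshape(N, H, W, Cout).transpose(0, 3, 1, 2)

    def backward(g):
        g_flat = g.transpose(0, 2, 3, 1).reshape(-1, Cout)
        if w.requires_grad:
            # recompute the patch matrix rather than holding it in memory
            cols_b = _im2col(np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))), k, H, W)
            _accumulate(w, (g_flat.T @ cols_b).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            _accumulate(b, g_flat.sum(axis=0))
        if x.requires_grad or x._backward is not None:
            dcols = (g_flat @ wmat).reshape(N, H, W, C, k, k).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + H, j:j + W] += dcols[:, :, :, :, i, j]
            _accumulate(x, dxp[:, :, p:p + H, p:p + W] if p else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2x2 requires even spatial dims")
    H2, W2 = H // 2, W // 2
    blocks = x.data.reshape(N, C, H2, 2, W2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H2, W2, 4)
    idx = blocks.argmax(axis=-1)
    out_data = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        db = np.zeros((N, C, H2, W2, 4), dtype=np.float32)
        np.put_along_axis(db, idx[..., None], g[..., None], axis=-1)
        dx = db.reshape(N, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)
        _accumulate(x, dx)

    return _node(out_data, (x,), backward)


def upsample2x(x: Tensor) -> Tensor:
    """2x nearest-neighbour upsampling."""
    N, C, H, W = x.data.shape
    out_data = np.broadcast_to(
        x.data[:, :, :, None, :, None], (N, C, H, 2, W, 2)
    ).reshape(N, C, 2 * H, 2 * W).copy()

    def backward(g):
        _accumulate(x, g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    return _node(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# Reductions used by the attention modules
# ---------------------------------------------------------------------------

def mean_hw(x: Tensor) -> Tensor:
    """Global average pool over H, W -> (N, C, 1, 1)."""
    N, C, H, W = x.data.shape
    out_data = x.data.mean(axis=(2, 3), keepdims=True)

    def backward(g):
        _accumulate(x, np.broadcast_to(g / (H * W), x.data.shape).astype(np.float32))

    return _node(out_data, (x,), backward)


def max_hw(x: Tensor) -> Tensor:
    """Global max pool over H, W -> (N, C, 1, 1)."""
    N, C, H, W = x.data.shape
    flat = x.data.reshape(N, C, -1)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1).reshape(N, C, 1, 1)

    def backward(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g.reshape(N, C, 1), axis=-1)
        _accumulate(x, dflat.reshape(x.data.shape))

    return _node(out_data, (x,), backward)


def mean_c(x: Tensor) -> Tensor:
    """Channel-axis mean -> (N, 1, H, W)."""
    C = x.data.shape[1]
    out_data = x.data.mean(axis=1, keepdims=True)

    def backward(g):
        _accumulate(x, np.broadcast_to(g / C, x.data.shape).astype(np.float32))

    return _node(out_data, (x,), backward)


def max_c(x: Tensor) -> Tensor:
    """Channel-axis max -> (N, 1, H, W)."""
    idx = x.data.argmax(axis=1, keepdims=True)
    out_data = np.take_along_axis(x.data, idx, axis=1)

    def backward(g):
        dx = np.zeros_like(x.data)
        np.put_along_axis(dx, idx, g, axis=1)
        _accumulate(x, dx)

    return _node(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# Batch normalization (training-mode primitive)
# ---------------------------------------------------------------------------

def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Per-channel batch normalization over (N, H, W).

    Returns (output tensor, batch_mean, batch_var) — the statistics are plain
    arrays for the caller to fold into running estimates.
    """
    N, C, H, W = x.data.shape
    m = N * H * W
    mu = x.data.mean(axis=(0, 2, 3))
    var = x.data.var(axis=(0, 2, 3))
    std = np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) / std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            _accumulate(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            _accumulate(beta, g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._backward is not None:
            gg = g * gamma.data[None, :, None, None]
            mean_gg = gg.mean(axis=(0, 2, 3), keepdims=True)
            mean_gg_xhat = (gg * xhat).mean(axis=(0, 2, 3), keepdims=True)
            dx = (gg - mean_gg - xhat * mean_gg_xhat) / std[None, :, None, None]
            _accumulate(x, dx.astype(np.float32))

    out = _node(out_data, (x, gamma, beta), backward)
    return out, mu, var


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray):
    """Mean per-pixel cross entropy.

    logits: (N, k, H, W); labels: (N, H, W) integer classes.
    Returns (scalar loss tensor, probability array).
    """
    probs = softmax(logits.data, axis=1)
    N, k, H, W = logits.data.shape
    labels = np.asarray(labels)
    if labels.shape != (N, H, W):
        raise ValueError(f"label shape {labels.shape} != {(N, H, W)}")
    picked = np.take_along_axis(probs, labels[:, None, :, :], axis=1)[:, 0]
    n_pix = N * H * W
    loss_val = -np.log(np.maximum(picked, 1e-12)).sum() / n_pix

    def backward(g):
        onehot = np.zeros_like(probs)
        np.put_along_axis(onehot, labels[:, None, :, :], 1.0, axis=1)
        _accumulate(logits, (probs - onehot) * (float(g) / n_pix))

    return _node(np.float32(loss_val), (logits,), backward), probs
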