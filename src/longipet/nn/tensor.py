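"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: each :class:`Tensor` wraps an
``ndarray`` and records the operation that produced it.  ``backward()``
walks the tape in reverse topological order and accumulates gradients.
Only the operations needed by the segmentation network are implemented,
and the expensive ones (3-D convolution, normalisation layers, softmax)
are fused single nodes with hand-written adjoints rather than long
chains of primitive ops.

All shapes follow the (N, C, D, H, W) convention for volumetric feature
maps and (..., tokens, channels) for attention.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "cat",
    "matmul",
    "softmax",
    "log_softmax",
    "sigmoid",
    "leaky_relu",
    "relu",
    "gelu",
    "conv3d",
    "instance_norm3d",
    "layer_norm",
    "upsample_nearest3d",
    "avgpool_nearest3d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra dims
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ------------------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- graph helpers --------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accumulate(-g)

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g, b.shape))

        return Tensor._make(a.data - b.data, (a, b), bw)

    def __rsub__(self, other):
        return Tensor(np.asarray(other, dtype=self.dtype)) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return Tensor(np.asarray(other, dtype=self.dtype)) / self

    def __pow__(self, k: float):
        a = self

        def bw(g):
            a._accumulate(g * k * a.data ** (k - 1))

        return Tensor._make(a.data**k, (a,), bw)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(gg, a.shape))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def bw(g):
            a._accumulate(g.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accumulate(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bw)

    def pad(self, pad_width):
        """Zero padding; ``pad_width`` as for ``np.pad``."""
        a = self
        pw = tuple((int(lo), int(hi)) for lo, hi in pad_width)

        def bw(g):
            sl = tuple(slice(lo, g.shape[i] - hi if hi else None) for i, (lo, hi) in enumerate(pw))
            a._accumulate(g[sl])

        return Tensor._make(np.pad(a.data, pw), (a,), bw)

    def __getitem__(self, idx):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

        return Tensor._make(a.data[idx], (a,), bw)

    def roll(self, shifts, axes):
        a = self

        def bw(g):
            a._accumulate(np.roll(g, tuple(-s for s in shifts), axes))

        return Tensor._make(np.roll(a.data, shifts, axes), (a,), bw)

    # -- elementwise ----------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bw)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bw(g):
            a._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), bw)


# ----------------------------------------------------------------------
# free functions
# ----------------------------------------------------------------------

def cat(tensors, axis=0):
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(data, tuple(tensors), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product over the last two axes."""

    def bw(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.shape))

    return Tensor._make(np.matmul(a.data, b.data), (a, b), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))

    return Tensor._make(s, (x,), bw)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    shifted = x.data - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = shifted - lse
    p = np.exp(out)

    def bw(g):
        x._accumulate(g - p * g.sum(axis=axis, keepdims=True))

    return Tensor._make(out, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable in both tails
    pos = x.data >= 0
    e = np.exp(np.where(pos, -x.data, x.data))
    s = np.where(pos, 1.0 / (1.0 + e), e / (1.0 + e))

    def bw(g):
        x._accumulate(g * s * (1.0 - s))

    return Tensor._make(s, (x,), bw)


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, slope * x.data)

    def bw(g):
        x._accumulate(np.where(mask, g, slope * g))

    return Tensor._make(out, (x,), bw)


def relu(x: Tensor) -> Tensor:
    return leaky_relu(x, 0.0)


def gelu(x: Tensor) -> Tensor:
    """tanh approximation of GELU."""
    c = np.sqrt(2.0 / np.pi)
    u = c * (x.data + 0.044715 * x.data**3)
    t = np.tanh(u)
    out = 0.5 * x.data * (1.0 + t)

    def bw(g):
        du = c * (1.0 + 3 * 0.044715 * x.data**2)
        dt = (1.0 - t * t) * du
        x._accumulate(g * (0.5 * (1.0 + t) + 0.5 * x.data * dt))

    return Tensor._make(out, (x,), bw)


# ----------------------------------------------------------------------
# fused volumetric ops
# ----------------------------------------------------------------------

def _windows(x: np.ndarray, kshape, stride: int) -> np.ndarray:
    """Strided view (N,C,do,ho,wo,kd,kh,kw) over a padded input."""
    v = np.lib.stride_tricks.sliding_window_view(x, kshape, axis=(2, 3, 4))
    if stride != 1:
        v = v[:, :, ::stride, ::stride, ::stride]
    return v


def _use_im2col(kshape) -> bool:
    # small kernels are faster via the offset loop (contiguous BLAS calls)
    return int(np.prod(kshape)) > 27


def _conv3d_raw(x: np.ndarray, w: np.ndarray, stride: int, padding: int) -> np.ndarray:
    """Cross-correlation of (N,C,D,H,W) with (Co,C,kd,kh,kw)."""
    co, ci, kd, kh, kw = w.shape
    assert ci == x.shape[1], f"channel mismatch {ci} != {x.shape[1]}"
    if padding:
        x = np.pad(x, ((0, 0), (0, 0)) + ((padding, padding),) * 3)
    if _use_im2col((kd, kh, kw)):
        v = _windows(x, (kd, kh, kw), stride)
        out = np.tensordot(v, w, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
        return np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))
    do = (x.shape[2] - kd) // stride + 1
    ho = (x.shape[3] - kh) // stride + 1
    wo = (x.shape[4] - kw) // stride + 1
    out = np.zeros((x.shape[0], do, ho, wo, co), dtype=x.dtype)
    for i in range(kd):
        for j in range(kh):
            for k in range(kw):
                patch = x[:, :, i : i + stride * do : stride,
                          j : j + stride * ho : stride,
                          k : k + stride * wo : stride]
                out += np.tensordot(patch, w[:, :, i, j, k], axes=([1], [1]))
    return np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 1) -> Tensor:
    """3-D convolution (cross-correlation) with explicit adjoint.

    The kernel is accumulated offset-by-offset, which keeps memory flat
    (no im2col buffer) while every inner product is a large BLAS call.
    """
    out_data = _conv3d_raw(x.data, w.data, stride, padding)
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1, 1)
    co, ci, kd, kh, kw = w.shape
    n = x.shape[0]
    do, ho, wo = out_data.shape[2:]

    def bw(g):
        # g: (N,Co,do,ho,wo)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        xpad = x.data
        if padding:
            xpad = np.pad(xpad, ((0, 0), (0, 0)) + ((padding, padding),) * 3)
        if w.requires_grad:
            if _use_im2col((kd, kh, kw)):
                v = _windows(xpad, (kd, kh, kw), stride)
                # sum over N and output positions -> (Co, C, kd, kh, kw)
                gw = np.tensordot(g, v, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
            else:
                gw = np.zeros_like(w.data)
                for i in range(kd):
                    for j in range(kh):
                        for k in range(kw):
                            patch = xpad[:, :, i : i + stride * do : stride,
                                         j : j + stride * ho : stride,
                                         k : k + stride * wo : stride]
                            gw[:, :, i, j, k] = np.tensordot(
                                g, patch, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
            w._accumulate(gw)
        if x.requires_grad:
            if stride == 1 and _use_im2col((kd, kh, kw)):
                # adjoint of correlation = full correlation with the
                # spatially flipped, channel-transposed kernel
                wf = w.data[:, :, ::-1, ::-1, ::-1]
                gpad = np.pad(g, ((0, 0), (0, 0)) + tuple(
                    (k - 1, k - 1) for k in (kd, kh, kw)))
                vg = _windows(gpad, (kd, kh, kw), 1)
                gx = np.tensordot(vg, wf, axes=([1, 5, 6, 7], [0, 2, 3, 4]))
                gx = gx.transpose(0, 4, 1, 2, 3)
                if padding:
                    gx = gx[:, :, padding:-padding, padding:-padding, padding:-padding]
            else:
                gx_pad = np.zeros(xpad.shape, dtype=xpad.dtype)
                for i in range(kd):
                    for j in range(kh):
                        for k in range(kw):
                            contrib = np.tensordot(
                                g, w.data[:, :, i, j, k], axes=([1], [0]))
                            contrib = contrib.transpose(0, 4, 1, 2, 3)
                            gx_pad[:, :, i : i + stride * do : stride,
                                   j : j + stride * ho : stride,
                                   k : k + stride * wo : stride] += contrib
                gx = gx_pad
                if padding:
                    gx = gx[:, :, padding:-padding, padding:-padding, padding:-padding]
            x._accumulate(gx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, bw)


def instance_norm3d(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise each (sample, channel) over its spatial extent."""
    ax = (2, 3, 4)
    mu = x.data.mean(axis=ax, keepdims=True)
    var = x.data.var(axis=ax, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gview = gamma.data.reshape(1, -1, 1, 1, 1)
    out = xhat * gview + beta.data.reshape(1, -1, 1, 1, 1)
    m = float(np.prod([x.shape[a] for a in ax]))

    def bw(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3, 4)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            gh = g * gview
            s1 = gh.sum(axis=ax, keepdims=True)
            s2 = (gh * xhat).sum(axis=ax, keepdims=True)
            x._accumulate(inv * (gh - (s1 + xhat * s2) / m))

    return Tensor._make(out, (x, gamma, beta), bw)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise over the trailing (channel) axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = xhat * gamma.data + beta.data
    m = float(x.shape[-1])

    def bw(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).reshape(-1, x.shape[-1]).sum(axis=0))
        if beta.requires_grad:
            beta._accumulate(g.reshape(-1, x.shape[-1]).sum(axis=0))
        if x.requires_grad:
            gh = g * gamma.data
            s1 = gh.mean(axis=-1, keepdims=True)
            s2 = (gh * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (gh - s1 - xhat * s2))

    return Tensor._make(out, (x, gamma, beta), bw)


def upsample_nearest3d(x: Tensor, factor: int = 2) -> Tensor:
    f = int(factor)
    out = x.data.repeat(f, axis=2).repeat(f, axis=3).repeat(f, axis=4)

    def bw(g):
        n, c, d, h, w = x.shape
        gr = g.reshape(n, c, d, f, h, f, w, f).sum(axis=(3, 5, 7))
        x._accumulate(gr)

    return Tensor._make(out, (x,), bw)


def avgpool_nearest3d(x: Tensor, factor: int = 2) -> Tensor:
    f = int(factor)
    n, c, d, h, w = x.shape
    out = x.data.reshape(n, c, d // f, f, h // f, f, w // f, f).mean(axis=(3, 5, 7))

    def bw(g):
        gg = g / float(f**3)
        x._accumulate(gg.repeat(f, axis=2).repeat(f, axis=3).repeat(f, axis=4))

    return Tensor._make(out, (x,), bw)
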