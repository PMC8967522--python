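"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations that
produced it; :meth:`Tensor.backward` walks the tape in reverse topological
order and accumulates gradients.  Only the operations needed by the
segmentation network are provided (broadcast arithmetic, matmul, ReLU,
sigmoid, reductions, 2D convolution / transposed convolution / max-pooling,
channel concatenation).  Everything runs in float64: at desk scale the
arrays are small and exact agreement with loop-based oracles matters more
than speed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "relu",
    "sigmoid",
    "concat",
    "reduce_sum",
    "reduce_mean",
    "reduce_max",
    "conv2d",
    "conv_transpose2d",
    "maxpool2d",
]


class Tensor:
    """A node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every graph leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep graphs exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
        """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
        while grad.ndim > len(shape):
            grad = grad.sum(axis=0)
        for ax, n in enumerate(shape):
            if n == 1 and grad.shape[ax] != 1:
                grad = grad.sum(axis=ax, keepdims=True)
        return grad

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(Tensor._unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(Tensor._unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(Tensor._unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(Tensor._unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(Tensor._unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    Tensor._unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    def reshape(self, *shape):
        orig = self.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)


# ---------------------------------------------------------------------------
# Elementwise nonlinearities
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic
    out = np.empty_like(x.data)
    pos = x.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    ex = np.exp(x.data[~pos])
    out[~pos] = ex / (1.0 + ex)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out * (1.0 - out))

    return Tensor._make(out, (x,), backward)


# ---------------------------------------------------------------------------
# Reductions and shape ops
# ---------------------------------------------------------------------------

def reduce_sum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def backward(g):
        if not x.requires_grad:
            return
        if axis is None:
            x._accumulate(np.broadcast_to(g, x.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g, x.shape).copy())

    return Tensor._make(x.data.sum(axis=axis, keepdims=keepdims), (x,), backward)


def reduce_mean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = x.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([x.shape[a] for a in axes]))
    return reduce_sum(x, axis=axis, keepdims=keepdims) * (1.0 / n)


def reduce_max(x: Tensor, axis, keepdims: bool = False) -> Tensor:
    out = x.data.max(axis=axis, keepdims=True)
    # ties share the gradient equally
    mask = (x.data == out).astype(np.float64)
    mask /= mask.sum(axis=axis, keepdims=True)

    def backward(g):
        if not x.requires_grad:
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(mask * g)

    result = out if keepdims else out.squeeze(axis=axis)
    return Tensor._make(result, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


# ---------------------------------------------------------------------------
# 2D convolution family (NCHW, stride 1, symmetric zero padding)
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """2D convolution (cross-correlation) with stride 1.

    ``x``: (N, Cin, H, W); ``w``: (Cout, Cin, kh, kw); ``b``: (Cout,).
    """
    n, cin, h, wd = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"input has {cin} channels but kernel expects {cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    oh = h + 2 * padding - kh + 1
    ow = wd + 2 * padding - kw + 1
    out = np.zeros((n, cout, oh, ow))
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i : i + oh, j : j + ow]
            # (N,Cin,OH,OW) x (Cout,Cin) -> (N,OH,OW,Cout)
            out += np.tensordot(patch, w.data[:, :, i, j], axes=([1], [1])).transpose(
                0, 3, 1, 2
            )
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + oh, j : j + ow] += np.tensordot(
                        g, w.data[:, :, i, j], axes=([1], [0])
                    ).transpose(0, 3, 1, 2)
            if padding:
                gx = gxp[:, :, padding:-padding, padding:-padding]
            else:
                gx = gxp
            x._accumulate(gx)
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    patch = xp[:, :, i : i + oh, j : j + ow]
                    gw[:, :, i, j] = np.tensordot(
                        g, patch, axes=([0, 2, 3], [0, 2, 3])
                    )
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution with kernel 2x2 and stride 2 (exact upsampling).

    ``x``: (N, Cin, H, W); ``w``: (Cin, Cout, 2, 2); output (N, Cout, 2H, 2W).
    Kernel and stride both 2, so output windows never overlap.
    """
    n, cin, h, wd = x.shape
    cin_w, cout, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"input has {cin} channels but kernel expects {cin_w}")
    out = np.zeros((n, cout, 2 * h, 2 * wd))
    for i in range(kh):
        for j in range(kw):
            out[:, :, i::2, j::2] = np.tensordot(
                x.data, w.data[:, :, i, j], axes=([1], [0])
            ).transpose(0, 3, 1, 2)
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for i in range(kh):
                for j in range(kw):
                    gx += np.tensordot(
                        g[:, :, i::2, j::2], w.data[:, :, i, j], axes=([1], [1])
                    ).transpose(0, 3, 1, 2)
            x._accumulate(gx)
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    gw[:, :, i, j] = np.tensordot(
                        x.data, g[:, :, i::2, j::2], axes=([0, 2, 3], [0, 2, 3])
                    )
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k max pooling (H, W divisible by k)."""
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial size ({h}, {w}) not divisible by pool size {k}")
    hv, wv = h // k, w // k
    windows = (
        x.data.reshape(n, c, hv, k, wv, k).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, hv, wv, k * k
        )
    )
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gw = np.zeros_like(windows)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gx = (
            gw.reshape(n, c, hv, wv, k, k)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        x._accumulate(gx)

    return Tensor._make(out, (x,), backward)
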