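"""Minimal reverse-mode automatic differentiation on numpy arrays.

The generative model in this package is a few dozen dense, convolutional
and recurrent operations; this module provides exactly those primitives as
a small tape-based autodiff engine. Arrays are float32 throughout. The
design follows the classic define-by-run pattern: every operation returns
a :class:`Tensor` holding its value, its parents and a closure that
accumulates gradients into the parents during :meth:`Tensor.backward`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "matmul",
    "concat",
    "stack",
    "relu",
    "tanh",
    "sigmoid",
    "exp",
    "cross_entropy_logits",
    "softmax",
]

_DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=_DTYPE)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(p for p in parents if p.requires_grad)
        self._backward = backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph traversal -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` into every reachable parameter."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free the tape

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(_DTYPE, copy=True)
        else:
            self.grad += grad

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else constant(other)
        out_data = self.data + other.data

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            a._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else constant(other)
        return self + (-other)

    def __rsub__(self, other):
        return constant(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else constant(other)
        out_data = self.data * other.data

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __getitem__(self, key):
        out_data = self.data[key]

        def bwd(g, a=self, key=key):
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            a._accum(full)

        return Tensor(out_data, parents=(self,), backward=bwd)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def bwd(g, a=self, orig=orig):
            a._accum(g.reshape(orig))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def transpose(self, *axes):
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def bwd(g, a=self, inv=tuple(inv)):
            a._accum(g.transpose(inv))

        return Tensor(out_data, parents=(self,), backward=bwd)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g, a=self, axis=axis, keepdims=keepdims):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).astype(_DTYPE))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def parameter(data) -> Tensor:
    """A trainable leaf tensor."""
    return Tensor(data, requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product; supports stacked leading dimensions on ``a``."""
    out_data = a.data @ b.data

    def bwd(g, a=a, b=b):
        if a.requires_grad:
            a._accum(g @ b.data.T if b.data.ndim == 2 else g @ np.swapaxes(b.data, -1, -2))
        if b.requires_grad:
            if a.data.ndim == 2:
                b._accum(a.data.T @ g)
            else:
                # stacked a: contract all leading axes
                ad = a.data.reshape(-1, a.data.shape[-1])
                gd = g.reshape(-1, g.shape[-1])
                b._accum(ad.T @ gd)

    return Tensor(out_data, parents=(a, b), backward=bwd)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g, tensors=tensors, axis=axis, offsets=offsets):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


def stack(tensors, axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g, tensors=tuple(tensors), axis=axis):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def bwd(g, x=x, mask=mask):
        x._accum(g * mask)

    return Tensor(out_data, parents=(x,), backward=bwd)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def bwd(g, x=x, y=out_data):
        x._accum(g * (1.0 - y * y))

    return Tensor(out_data, parents=(x,), backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g, x=x, y=out_data):
        x._accum(g * y * (1.0 - y))

    return Tensor(out_data, parents=(x,), backward=bwd)


def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)

    def bwd(g, x=x, y=out_data):
        x._accum(g * y)

    return Tensor(out_data, parents=(x,), backward=bwd)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Numerically stable softmax on a plain array (inference paths)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_logits(logits: Tensor, target_index: np.ndarray) -> Tensor:
    """Per-row categorical cross-entropy from unnormalised logits.

    ``logits`` has shape (M, C); ``target_index`` is an int array (M,).
    Returns a Tensor of shape (M,). Fused log-softmax for stability.
    """
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    zs = z - zmax
    lse = np.log(np.exp(zs).sum(axis=1, keepdims=True))
    logp = zs - lse
    m = np.arange(z.shape[0])
    out_data = -logp[m, target_index]
    p = np.exp(logp)

    def bwd(g, logits=logits, p=p, m=m, target_index=target_index):
        gp = p * g[:, None]
        gp[m, target_index] -= g
        logits._accum(gp)

    return Tensor(out_data, parents=(logits,), backward=bwd)
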