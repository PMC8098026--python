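"""Minimal reverse-mode automatic differentiation on numpy arrays.

Everything runs in float64.  A :class:`Tensor` wraps an ndarray and records
its parents plus a backward closure; :meth:`Tensor.backward` runs a reverse
topological sweep accumulating gradients.  Only the operations the model
needs are implemented (elementwise arithmetic, matmul, reductions, indexing,
softmax, a valid-padding 2-D convolution, embedding lookup).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "embedding", "conv2d_valid", "softmax", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (the inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ meta
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    # -------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
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
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = g.copy()
            else:
                node.grad = node.grad + g
            if node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # ------------------------------------------------------------ arithmetic
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data
        a_shape, b_shape = self.data.shape, other.data.shape
        return Tensor(
            out_data,
            _parents=(self, other),
            _backward=lambda g: (_unbroadcast(g, a_shape), _unbroadcast(g, b_shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        return Tensor(
            a * b,
            _parents=(self, other),
            _backward=lambda g: (
                _unbroadcast(g * b, a.shape),
                _unbroadcast(g * a, b.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        return Tensor(
            a / b,
            _parents=(self, other),
            _backward=lambda g: (
                _unbroadcast(g / b, a.shape),
                _unbroadcast(-g * a / (b * b), b.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        a = self.data
        return Tensor(
            a**p,
            _parents=(self,),
            _backward=lambda g: (g * p * a ** (p - 1),),
        )

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        out = a @ b

        def bw(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor(out, _parents=(self, other), _backward=bw)

    # ------------------------------------------------------------- elementwise
    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, _parents=(self,), _backward=lambda g: (g * out,))

    def log(self):
        a = self.data
        return Tensor(np.log(a), _parents=(self,), _backward=lambda g: (g / a,))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor(out, _parents=(self,), _backward=lambda g: (g / (2.0 * out),))

    def relu(self):
        mask = self.data > 0
        return Tensor(
            np.where(mask, self.data, 0.0),
            _parents=(self,),
            _backward=lambda g: (g * mask,),
        )

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(out, _parents=(self,), _backward=lambda g: (g * out * (1 - out),))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor(out, _parents=(self,), _backward=lambda g: (g * (1 - out * out),))

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        return Tensor(
            np.clip(self.data, lo, hi),
            _parents=(self,),
            _backward=lambda g: (g * mask,),
        )

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        shape = self.data.shape
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            g2 = g
            if not keepdims:
                g2 = np.expand_dims(g2, axis)
            return (np.broadcast_to(g2, shape).copy(),)

        return Tensor(out, _parents=(self,), _backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ----------------------------------------------------------- shape/indexing
    def reshape(self, *shape):
        orig = self.data.shape
        return Tensor(
            self.data.reshape(*shape),
            _parents=(self,),
            _backward=lambda g: (g.reshape(orig),),
        )

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes),
            _parents=(self,),
            _backward=lambda g: (g.transpose(inv),),
        )

    def swapaxes(self, a: int, b: int):
        return Tensor(
            np.swapaxes(self.data, a, b),
            _parents=(self,),
            _backward=lambda g: (np.swapaxes(g, a, b),),
        )

    def __getitem__(self, idx):
        shape = self.data.shape

        def bw(g):
            out = np.zeros(shape, dtype=np.float64)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor(self.data[idx], _parents=(self,), _backward=bw)


# ----------------------------------------------------------------- functions
def embedding(table: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``table[indices]`` with scatter-add backward."""
    indices = np.asarray(indices)
    shape = table.data.shape

    def bw(g):
        out = np.zeros(shape, dtype=np.float64)
        np.add.at(out, indices, g)
        return (out,)

    return Tensor(table.data[indices], _parents=(table,), _backward=bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        return (y * (g - (g * y).sum(axis=axis, keepdims=True)),)

    return Tensor(y, _parents=(x,), _backward=bw)


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate(datas, axis=axis), _parents=tuple(tensors), _backward=bw
    )


def conv2d_valid(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """2-D convolution (cross-correlation), stride 1, no padding.

    x: (B, C_in, H, W); weight: (C_out, C_in, kh, kw); bias: (C_out,)
    returns (B, C_out, H-kh+1, W-kw+1).
    """
    xb, wb, bb = x.data, weight.data, bias.data
    B, Cin, H, W = xb.shape
    Cout, _, kh, kw = wb.shape
    if H < kh or W < kw:
        raise ValueError(
            f"input {H}x{W} smaller than kernel {kh}x{kw}"
        )
    win = np.lib.stride_tricks.sliding_window_view(xb, (kh, kw), axis=(2, 3))
    # win: (B, Cin, H', W', kh, kw)
    out = np.einsum("bihwkl,oikl->bohw", win, wb, optimize=True) + bb[:, None, None]
    Hp, Wp = H - kh + 1, W - kw + 1

    def bw(g):
        gw = np.einsum("bihwkl,bohw->oikl", win, g, optimize=True)
        gb = g.sum(axis=(0, 2, 3))
        gx = np.zeros_like(xb)
        for k in range(kh):
            for l in range(kw):
                gx[:, :, k : k + Hp, l : l + Wp] += np.einsum(
                    "bohw,oi->bihw", g, wb[:, :, k, l], optimize=True
                )
        return gx, gw, gb

    return Tensor(out, _parents=(x, weight, bias), _backward=bw)
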