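"""Minimal reverse-mode automatic differentiation over numpy arrays.

All model components in this package are built on :class:`Tensor`, a thin
float64 wrapper around ``numpy.ndarray`` that records the operations applied
to it and can replay them in reverse to accumulate gradients.  The op set is
deliberately small: elementwise arithmetic, matmul, reductions, reshaping,
softmax/log-softmax, a 3-D convolution, and a gradient-reversal op.  Every op
with a hand-written backward rule is checked against central finite
differences in the test suite.

Design notes
------------
* float64 throughout — gradient checks at 1e-4 relative tolerance need the
  head-room, and the models here are small enough that speed is unaffected.
* Gradients are accumulated into ``Tensor.grad`` (a plain ndarray) during
  :meth:`Tensor.backward`; call :func:`zero_grad` / ``Optimizer.zero_grad``
  between steps.
* Broadcasting follows numpy; the backward pass un-broadcasts by summing the
  broadcast axes.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "stack",
    "softmax",
    "log_softmax",
    "grad_reverse",
    "conv3d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the local backward rule that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple["Tensor", ...] = (),
                 _backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this tensor (topological order)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack_.append((p, False))
        grads: dict[int, np.ndarray] = {}
        grads[id(self)] = (np.ones_like(self.data) if grad is None
                           else np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node._accumulate(g)
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] += pg
                else:
                    grads[id(parent)] = pg

    # -------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = _ensure(other)
        out = Tensor(self.data + other.data, _parents=(self, other))
        out._backward = lambda g: (_unbroadcast(g, self.shape),
                                   _unbroadcast(g, other.shape))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-_ensure(other))

    def __rsub__(self, other):
        return _ensure(other) + (-self)

    def __mul__(self, other):
        other = _ensure(other)
        out = Tensor(self.data * other.data, _parents=(self, other))
        out._backward = lambda g: (_unbroadcast(g * other.data, self.shape),
                                   _unbroadcast(g * self.data, other.shape))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _ensure(other)
        out = Tensor(self.data / other.data, _parents=(self, other))
        out._backward = lambda g: (
            _unbroadcast(g / other.data, self.shape),
            _unbroadcast(-g * self.data / other.data ** 2, other.shape))
        return out

    def __rtruediv__(self, other):
        return _ensure(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def __matmul__(self, other):
        other = _ensure(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            da = g @ np.swapaxes(other.data, -1, -2)
            db = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(da, self.shape), _unbroadcast(db, other.shape)

        out._backward = bwd
        return out

    # --------------------------------------------------------------- unary ops
# NOTE: backward closures must capture plain ndarrays, never the output
# Tensor itself — a closure referencing its own Tensor forms a reference
# cycle that defers freeing whole computation graphs to the cyclic GC.

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: (g * y,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: (g * 0.5 / y,)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: (g * (1.0 - y ** 2),)
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: (g * y * (1.0 - y),)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        mask = self.data > 0
        out._backward = lambda g: (g * mask,)
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _parents=(self,))

        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g_ = g
            if not keepdims:
                g_ = np.expand_dims(g, axis)
            return (np.broadcast_to(g_, self.shape).copy(),)

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ shape juggle
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: (g.transpose(inv),)
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), _parents=(self,))
        out._backward = lambda g: (np.swapaxes(g, a, b),)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = bwd
        return out


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class Parameter(Tensor):
    """A trainable tensor (``requires_grad=True`` by construction)."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# --------------------------------------------------------------- free functions
def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [_ensure(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [_ensure(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))

    def bwd(g):
        pieces = np.split(g, len(tensors), axis=axis)
        return tuple(np.squeeze(p, axis=axis) for p in pieces)

    out._backward = bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Softmax with -inf support: fully masked entries get exactly zero mass."""
    z = x.data - np.max(x.data, axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, _parents=(x,))

    def bwd(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        return (y * (g - dot),)

    out._backward = bwd
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = np.max(x.data, axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = Tensor(z - lse, _parents=(x,))
    y = np.exp(out.data)

    def bwd(g):
        return (g - y * g.sum(axis=axis, keepdims=True),)

    out._backward = bwd
    return out


def grad_reverse(x: Tensor, strength: float = 1.0) -> Tensor:
    """Gradient reversal: identity forward, ``-strength * grad`` backward.

    Placing this in front of an auxiliary classifier turns that classifier's
    training signal into an adversarial penalty on the upstream features.
    """
    out = Tensor(x.data, _parents=(x,))
    out._backward = lambda g: (-strength * g,)
    return out


def lstm_pass(x: Tensor, w_x: Tensor, w_h: Tensor, b: Tensor,
              mask: np.ndarray, reverse: bool = False) -> Tensor:
    """One LSTM direction as a single fused op (manual BPTT backward).

    Gate order along the 4H axis: input, forget, cell, output.  At masked
    timesteps the hidden and cell state carry over unchanged and the output
    is zeroed, so padding at either end cannot influence valid positions.
    The fused formulation avoids building ~15 graph nodes per timestep.
    """
    B, T, _ = x.shape
    H = w_h.shape[0]
    xp = x.data @ w_x.data + b.data  # B,T,4H
    order = range(T - 1, -1, -1) if reverse else range(T)
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    # caches for backward, indexed by time
    I = np.empty((T, B, H)); F = np.empty((T, B, H))
    U = np.empty((T, B, H)); O = np.empty((T, B, H))
    TC = np.empty((T, B, H))           # tanh(c_cand)
    HP = np.empty((T, B, H)); CP = np.empty((T, B, H))  # carried-in states
    out = np.zeros((B, T, H))
    for t in order:
        HP[t], CP[t] = h, c
        pre = xp[:, t] + h @ w_h.data
        i = 1.0 / (1.0 + np.exp(-pre[:, :H]))
        f = 1.0 / (1.0 + np.exp(-pre[:, H:2 * H]))
        u = np.tanh(pre[:, 2 * H:3 * H])
        o = 1.0 / (1.0 + np.exp(-pre[:, 3 * H:]))
        c_cand = f * c + i * u
        tc = np.tanh(c_cand)
        h_cand = o * tc
        m = mask[:, t:t + 1]
        c = m * c_cand + (1.0 - m) * c
        h = m * h_cand + (1.0 - m) * h
        I[t], F[t], U[t], O[t], TC[t] = i, f, u, o, tc
        out[:, t] = h * m[:, 0:1]
    result = Tensor(out, _parents=(x, w_x, w_h, b))

    def bwd(g):
        dxp = np.zeros_like(xp)
        d_wh = np.zeros_like(w_h.data)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(list(order)):
            m = mask[:, t:t + 1]
            dh = g[:, t] * m + dh_next
            dh_cand = dh * m
            dh_carry = dh * (1.0 - m)
            dc_cand = dc_next * m
            dc_carry = dc_next * (1.0 - m)
            do = dh_cand * TC[t]
            dc_cand = dc_cand + dh_cand * O[t] * (1.0 - TC[t] ** 2)
            df = dc_cand * CP[t]
            di = dc_cand * U[t]
            du = dc_cand * I[t]
            dc_prev = dc_cand * F[t] + dc_carry
            dpre = np.concatenate([
                di * I[t] * (1.0 - I[t]),
                df * F[t] * (1.0 - F[t]),
                du * (1.0 - U[t] ** 2),
                do * O[t] * (1.0 - O[t])], axis=1)
            dxp[:, t] = dpre
            d_wh += HP[t].T @ dpre
            dh_next = dpre @ w_h.data.T + dh_carry
            dc_next = dc_prev
        dx = dxp @ w_x.data.T
        d_wx = np.einsum("btd,bth->dh", x.data, dxp, optimize=True)
        db = dxp.sum(axis=(0, 1))
        return dx, d_wx, d_wh, db

    result._backward = bwd
    return result


def _extract_patches(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """Sliding k×k×k windows of padded input xp (B,C,D,H,W) with stride."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k),
                                                   axis=(2, 3, 4))
    return win[:, :, ::stride, ::stride, ::stride]


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """3-D cross-correlation. x: (B,C,D,H,W), w: (O,C,k,k,k), b: (O,)."""
    k = w.shape[-1]
    xp = np.pad(x.data, ((0, 0), (0, 0)) + ((padding, padding),) * 3)
    patches = _extract_patches(xp, k, stride)  # B,C,Do,Ho,Wo,k,k,k
    y = np.einsum("bcxyzijk,ocijk->boxyz", patches, w.data, optimize=True)
    if b is not None:
        y = y + b.data[None, :, None, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _parents=parents)
    out_shape = y.shape

    def bwd(g):
        dw = np.einsum("bcxyzijk,boxyz->ocijk", patches, g, optimize=True)
        dxp = np.zeros_like(xp)
        _, _, Do, Ho, Wo = out_shape
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    # y[b,o,x,y,z] uses xp[b,c,stride*x+i,stride*y+j,stride*z+l]
                    contrib = np.einsum("boxyz,oc->bcxyz", g,
                                        w.data[:, :, i, j, l], optimize=True)
                    dxp[:, :,
                        i:i + stride * Do:stride,
                        j:j + stride * Ho:stride,
                        l:l + stride * Wo:stride] += contrib
        if padding:
            dx = dxp[:, :, padding:-padding, padding:-padding,
                     padding:-padding]
        else:
            dx = dxp
        if b is None:
            return dx, dw
        db = g.sum(axis=(0, 2, 3, 4))
        return dx, dw, db

    out._backward = bwd
    return out
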