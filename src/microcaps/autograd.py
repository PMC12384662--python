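"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the micro-capsule network needs: broadcasting
arithmetic, reductions, reshape, ReLU, 2-D convolution (NHWC), softmax, and
two-operand einsum. Gradients are accumulated by a topological sweep over the
recorded tape. Everything is float64 for numerical transparency; the model is
small enough that speed is not a concern.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "softmax", "einsum", "relu", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor._from_op(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        return Tensor._from_op(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return Tensor._from_op(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**exponent
        return Tensor._from_op(
            out_data,
            (self,),
            lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    # -- shape & reductions ---------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        return Tensor._from_op(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(orig),)
        )

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._from_op(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def sqrt(self):
        return self**0.5

    # -- autodiff driver ------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor._from_op(x.data * mask, (x,), lambda g: (g * mask,))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        return (y * (g - (g * y).sum(axis=axis, keepdims=True)),)

    return Tensor._from_op(y, (x,), backward)


def einsum(spec: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum; each index of either operand must appear in the
    output or in the other operand (true for all contractions used here)."""
    lhs, out_idx = spec.split("->")
    a_idx, b_idx = lhs.split(",")

    def backward(g):
        ga = np.einsum(f"{out_idx},{b_idx}->{a_idx}", g, b.data, optimize=True)
        gb = np.einsum(f"{out_idx},{a_idx}->{b_idx}", g, a.data, optimize=True)
        return ga, gb

    return Tensor._from_op(
        np.einsum(spec, a.data, b.data, optimize=True), (a, b), backward
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor, padding: str = "valid") -> Tensor:
    """2-D convolution (cross-correlation), NHWC layout.

    x: (B, H, W, Cin); w: (kh, kw, Cin, Cout); b: (Cout,).
    padding 'same' keeps (H, W); 'valid' shrinks by kernel-1.
    """
    kh, kw, cin, cout = w.shape
    if padding == "same":
        ph0, pw0 = (kh - 1) // 2, (kw - 1) // 2
        ph1, pw1 = kh - 1 - ph0, kw - 1 - pw0
    elif padding == "valid":
        ph0 = ph1 = pw0 = pw1 = 0
    else:
        raise ValueError(f"unknown padding {padding!r}")
    xp = np.pad(x.data, ((0, 0), (ph0, ph1), (pw0, pw1), (0, 0)))
    Bn, Hp, Wp, _ = xp.shape
    Ho, Wo = Hp - kh + 1, Wp - kw + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(
            f"input spatial size {x.shape[1:3]} smaller than kernel ({kh},{kw})"
        )
    patches = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    # patches: (B, Ho, Wo, Cin, kh, kw) -> (B*Ho*Wo, kh*kw*Cin) for BLAS matmul
    cols = np.ascontiguousarray(patches.transpose(0, 1, 2, 4, 5, 3)).reshape(
        Bn * Ho * Wo, kh * kw * cin
    )
    wmat = w.data.transpose(0, 1, 2, 3).reshape(kh * kw * cin, cout)
    out = (cols @ wmat).reshape(Bn, Ho, Wo, cout) + b.data

    def backward(g):
        gflat = g.reshape(Bn * Ho * Wo, cout)
        gw = (cols.T @ gflat).reshape(kh, kw, cin, cout)
        gb = g.sum(axis=(0, 1, 2))
        gxp = np.zeros_like(xp)
        # scatter each kernel offset's contribution back onto the padded input
        for i in range(kh):
            for j in range(kw):
                contrib = gflat @ w.data[i, j].T  # (B*Ho*Wo, Cin)
                gxp[:, i : i + Ho, j : j + Wo, :] += contrib.reshape(
                    Bn, Ho, Wo, cin
                )
        gx = gxp[:, ph0 : Hp - ph1, pw0 : Wp - pw1, :]
        return gx, gw, gb

    return Tensor._from_op(out, (x, w, b), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
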