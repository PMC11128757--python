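"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the volumetric attention classifier needs:
broadcast arithmetic, elementwise nonlinearities, axis reductions, 3D
convolution (stride 1, "same" zero padding, odd kernels) and non-overlapping
average pooling. Gradients are dense float64 arrays accumulated by a reverse
topological sweep.

The engine is deliberately small: no views sharing storage, no in-place ops,
no higher-order gradients. Determinism is inherited from numpy — identical
inputs and parameters produce bitwise-identical outputs and gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "conv3d",
    "avg_pool3d",
    "relu",
    "sigmoid",
    "log",
    "exp",
    "sqrt0",
    "gather_rows",
    "log_softmax",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # collapse extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph bookkeeping ---------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from a scalar output."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def _bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def _bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / float(other))

    def __pow__(self, p: float):
        p = float(p)
        out = Tensor(self.data ** p, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1.0))
        return out

    # -- reductions / shape --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def _bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


# -- elementwise nonlinearities ----------------------------------------

def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), _parents=(x,))
    out._backward = lambda g: x._accumulate(g * (x.data > 0.0))
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, _parents=(x,))
    out._backward = lambda g: x._accumulate(g * s * (1.0 - s))
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), _parents=(x,))
    out._backward = lambda g: x._accumulate(g / x.data)
    return out


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    out = Tensor(e, _parents=(x,))
    out._backward = lambda g: x._accumulate(g * e)
    return out


def sqrt0(x: Tensor) -> Tensor:
    """Square root with the subgradient 0 at 0.

    Used for L2 norms so that a loss that is exactly zero (attention equal
    to its prior) produces a zero — not infinite — gradient.
    """
    r = np.sqrt(x.data)
    out = Tensor(r, _parents=(x,))

    def _bw(g):
        safe = np.where(r > 0.0, r, 1.0)
        x._accumulate(np.where(r > 0.0, g * 0.5 / safe, 0.0))

    out._backward = _bw
    return out


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select x[i, idx[i]] for each row i of a 2D tensor."""
    idx = np.asarray(idx, dtype=np.intp)
    rows = np.arange(x.data.shape[0])
    out = Tensor(x.data[rows, idx], _parents=(x,))

    def _bw(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, (rows, idx), g)
        x._accumulate(gx)

    out._backward = _bw
    return out


def log_softmax(x: Tensor) -> Tensor:
    """Row-wise log-softmax of a 2D tensor, max-shifted for stability."""
    shift = x.data.max(axis=1, keepdims=True)  # constant w.r.t. the graph
    z = x + Tensor(-shift)
    return z - log(exp(z).sum(axis=1, keepdims=True))


# -- spatial operators -------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """3D convolution, stride 1, zero "same" padding.

    x: (N, C, D, H, W); w: (O, C, k, k, k) with k odd; b: (O,) or None.
    Implemented as a sum over the k^3 kernel offsets of channel-mixing
    tensordots, which keeps memory linear in the volume size.
    """
    N, C, D, H, W = x.data.shape
    O, C2, k, k2, k3 = w.data.shape
    if C2 != C or k != k2 or k != k3 or k % 2 != 1:
        raise ValueError(f"kernel shape {w.data.shape} incompatible with input {x.data.shape}")
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    out_data = np.zeros((N, O, D, H, W))
    for i in range(k):
        for j in range(k):
            for l in range(k):
                patch = xp[:, :, i:i + D, j:j + H, l:l + W]
                # (N,C,D,H,W) x (O,C) -> (N,O,D,H,W)
                out_data += np.einsum("ncdhw,oc->nodhw", patch, w.data[:, :, i, j, l], optimize=True)
    if b is not None:
        out_data += b.data[None, :, None, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _parents=parents)

    def _bw(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    patch = xp[:, :, i:i + D, j:j + H, l:l + W]
                    gw[:, :, i, j, l] = np.einsum("nodhw,ncdhw->oc", g, patch, optimize=True)
                    gxp[:, :, i:i + D, j:j + H, l:l + W] += np.einsum(
                        "nodhw,oc->ncdhw", g, w.data[:, :, i, j, l], optimize=True
                    )
        x._accumulate(gxp[:, :, p:p + D, p:p + H, p:p + W] if p else gxp)
        w._accumulate(gw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))

    out._backward = _bw
    return out


def avg_pool3d(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping average pooling by an integer factor on each axis."""
    N, C, D, H, W = x.data.shape
    f = int(factor)
    if D % f or H % f or W % f:
        raise ValueError(f"spatial dims {(D, H, W)} not divisible by pool factor {f}")
    r = x.data.reshape(N, C, D // f, f, H // f, f, W // f, f)
    out = Tensor(r.mean(axis=(3, 5, 7)), _parents=(x,))

    def _bw(g):
        gx = (
            g[:, :, :, None, :, None, :, None]
            * np.full((1, 1, 1, f, 1, f, 1, f), 1.0 / f**3)
        )
        x._accumulate(gx.reshape(N, C, D, H, W))

    out._backward = _bw
    return out


# -- optimizer ---------------------------------------------------------

class Adam:
    """Adaptive-moment gradient descent over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / (1.0 - self.b1**self.t)
            vhat = self.v[i] / (1.0 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
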