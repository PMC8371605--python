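"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network components in this package (Evoformer trunk, structure module,
loss heads) are small enough that a compact tape-based autodiff engine over
float64 numpy arrays is sufficient to train them on toy problems on a single
CPU. The engine supports exactly the primitives those components need:
broadcasting arithmetic, batched matmul, reductions, softmax, elementwise
nonlinearities, slicing/gather, concatenation and stacking.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`.
Every primitive is checked against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "astensor", "ParamStore", "Adam",
    "exp", "log", "sqrt", "tanh", "sigmoid", "relu", "softplus",
    "softmax", "clamp_max", "concatenate", "stack", "gather",
    "layer_norm", "linear", "cross_entropy",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the local backward rule that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, parents=(), backward=None, requires_grad=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p in self._parents)
        self.requires_grad = requires_grad

    # -- bookkeeping -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)

    def backward(self) -> None:
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=False)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        out = Tensor(self.data + other.data, (self, other))
        out._backward = lambda g: (self.accumulate(g), other.accumulate(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self.accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        out = Tensor(self.data * other.data, (self, other))
        out._backward = lambda g: (
            self.accumulate(g * other.data),
            other.accumulate(g * self.data),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        out = Tensor(self.data / other.data, (self, other))
        out._backward = lambda g: (
            self.accumulate(g / other.data),
            other.accumulate(-g * self.data / other.data**2),
        )
        return out

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, (self,))
        out._backward = lambda g: self.accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = astensor(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bw(g):
            a, b = self.data, other.data
            if b.ndim == 1:
                self.accumulate(np.expand_dims(g, -1) * b)
                other.accumulate(_unbroadcast((np.expand_dims(g, -1) * a).reshape(-1, b.shape[0]).sum(0), b.shape))
            elif a.ndim == 1:
                self.accumulate(g @ np.swapaxes(b, -1, -2))
                other.accumulate(np.outer(a, g))
            else:
                self.accumulate(g @ np.swapaxes(b, -1, -2))
                other.accumulate(np.swapaxes(a, -1, -2) @ g)

        out._backward = bw
        return out

    def __rmatmul__(self, other):
        return astensor(other) @ self

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), (self,))
        out._backward = lambda g: self.accumulate(g.reshape(orig))
        return out

    def swapaxes(self, a, b):
        out = Tensor(np.swapaxes(self.data, a, b), (self,))
        out._backward = lambda g: self.accumulate(np.swapaxes(g, a, b))
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), (self,))
        out._backward = lambda g: self.accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self.accumulate(full)

        out._backward = bw
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self.accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x, requires_grad=False)


# -- elementwise primitives ------------------------------------------------

def exp(x: Tensor) -> Tensor:
    x = astensor(x)
    y = np.exp(x.data)
    out = Tensor(y, (x,))
    out._backward = lambda g: x.accumulate(g * y)
    return out


def log(x: Tensor) -> Tensor:
    x = astensor(x)
    out = Tensor(np.log(x.data), (x,))
    out._backward = lambda g: x.accumulate(g / x.data)
    return out


def sqrt(x: Tensor) -> Tensor:
    x = astensor(x)
    y = np.sqrt(x.data)
    out = Tensor(y, (x,))
    out._backward = lambda g: x.accumulate(g * 0.5 / y)
    return out


def tanh(x: Tensor) -> Tensor:
    x = astensor(x)
    y = np.tanh(x.data)
    out = Tensor(y, (x,))
    out._backward = lambda g: x.accumulate(g * (1.0 - y**2))
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = astensor(x)
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -50, 50)))
    out = Tensor(y, (x,))
    out._backward = lambda g: x.accumulate(g * y * (1.0 - y))
    return out


def relu(x: Tensor) -> Tensor:
    x = astensor(x)
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0), (x,))
    out._backward = lambda g: x.accumulate(g * mask)
    return out


def softplus(x: Tensor) -> Tensor:
    x = astensor(x)
    y = np.logaddexp(0.0, x.data)
    out = Tensor(y, (x,))
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -50, 50)))
    out._backward = lambda g: x.accumulate(g * s)
    return out


def clamp_max(x: Tensor, hi: float) -> Tensor:
    """min(x, hi); gradient passes only where x < hi."""
    x = astensor(x)
    mask = x.data < hi
    out = Tensor(np.where(mask, x.data, hi), (x,))
    out._backward = lambda g: x.accumulate(g * mask)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = astensor(x)
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, (x,))

    def bw(g):
        x.accumulate(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    out._backward = bw
    return out


# -- structural primitives -------------------------------------------------

def concatenate(tensors, axis: int = -1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t.accumulate(piece)

    out._backward = bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), tensors)

    def bw(g):
        for i, t in enumerate(tensors):
            t.accumulate(np.take(g, i, axis=axis))

    out._backward = bw
    return out


def gather(x: Tensor, index: np.ndarray, axis: int = -1) -> Tensor:
    """take_along_axis with gradient scatter-add."""
    x = astensor(x)
    index = np.asarray(index)
    out = Tensor(np.take_along_axis(x.data, index, axis=axis), (x,))

    def bw(g):
        full = np.zeros_like(x.data)
        np.add.at(
            full,
            tuple(
                index if a == (axis % x.data.ndim) else np.indices(index.shape)[a]
                for a in range(x.data.ndim)
            ),
            g,
        )
        x.accumulate(full)

    out._backward = bw
    return out


# -- composite layers ------------------------------------------------------

def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / sqrt(var + eps) * gamma + beta


def linear(store: "ParamStore", name: str, x: Tensor, d_in: int, d_out: int,
           init: str = "lecun", bias: bool = True, bias_init: str = "zeros") -> Tensor:
    w = store.get(f"{name}.w", (d_in, d_out), init)
    y = astensor(x) @ w
    if bias:
        y = y + store.get(f"{name}.b", (d_out,), bias_init)
    return y


def cross_entropy(logits: Tensor, targets: np.ndarray,
                  mask: np.ndarray | None = None) -> Tensor:
    """Mean categorical cross-entropy over the last axis.

    ``targets`` are integer class indices with the same leading shape as
    ``logits``; entries where ``mask`` is false are excluded from the mean.
    """
    logits = astensor(logits)
    m = logits.data.max(axis=-1, keepdims=True)  # constant shift, no grad
    z = logits - m
    lse = log(exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    picked = gather(logp, np.expand_dims(targets, -1), axis=-1)
    nll = -picked.reshape(targets.shape)
    if mask is None:
        return nll.mean()
    mask = np.asarray(mask, dtype=float)
    total = mask.sum()
    if total == 0:
        return Tensor(0.0)
    return (nll * mask).sum() / float(total)


# -- parameters and optimizer ----------------------------------------------

_INITS = {
    "lecun": lambda rng, shape, fan_in: rng.normal(0.0, 1.0 / np.sqrt(fan_in), shape),
    "relu": lambda rng, shape, fan_in: rng.normal(0.0, np.sqrt(2.0 / fan_in), shape),
    "zeros": lambda rng, shape, fan_in: np.zeros(shape),
    "ones": lambda rng, shape, fan_in: np.ones(shape),
}


class ParamStore:
    """Named, lazily created trainable parameters.

    Parameters are created on first use with the requested initializer; the
    whole store serializes to a single ``.npz`` archive of named arrays.
    """

    def __init__(self, seed: int = 0):
        self.rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}

    def get(self, name: str, shape: tuple, init: str = "lecun") -> Tensor:
        if name not in self.params:
            fan_in = shape[0] if len(shape) > 1 else shape[0]
            data = _INITS[init](self.rng, shape, fan_in)
            self.params[name] = Tensor(data, requires_grad=True)
        t = self.params[name]
        if t.data.shape != tuple(shape):
            raise ValueError(
                f"parameter {name!r} has shape {t.data.shape}, requested {tuple(shape)}"
            )
        return t

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def save(self, path) -> None:
        np.savez(path, **{k: v.data for k, v in self.params.items()})

    def load(self, path) -> None:
        with np.load(path) as archive:
            for k in archive.files:
                self.params[k] = Tensor(archive[k], requires_grad=True)

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.params.values())


class Adam:
    """Adaptive-moment gradient descent over a :class:`ParamStore`."""

    def __init__(self, store: ParamStore, lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.store = store
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        for name, p in self.store.params.items():
            if p.grad is None:
                continue
            m = self._m.setdefault(name, np.zeros_like(p.data))
            v = self._v.setdefault(name, np.zeros_like(p.data))
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
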