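"""A small vectorized reverse-mode automatic differentiation engine.

Just enough machinery for the sequence models in this package: tensors
holding numpy arrays, a tape of operations with hand-written vector-Jacobian
products, and a topological-order backward pass.  Single-threaded numpy
keeps everything bit-for-bit reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_vjp", "requires_grad")

    def __init__(self, data, requires_grad=False, parents=(), vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._vjp = vjp

    @property
    def shape(self):
        return self.data.shape

    # -- graph machinery ------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._vjp is not None:
                t._vjp(t.grad)

    # -- operators ------------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def vjp(g):
            _accum(self, _unbroadcast(g, self.data.shape))
            _accum(other, _unbroadcast(g, other.data.shape))
        out._vjp = vjp
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def vjp(g):
            _accum(self, _unbroadcast(g * other.data, self.data.shape))
            _accum(other, _unbroadcast(g * self.data, other.data.shape))
        out._vjp = vjp
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def vjp(g):
            _accum(self, _unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                      self.data.shape))
            _accum(other, _unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                       other.data.shape))
        out._vjp = vjp
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def vjp(g):
            if self.requires_grad:
                buf = np.zeros_like(self.data)
                np.add.at(buf, key, g)
                _accum(self, buf)
        out._vjp = vjp
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._vjp = lambda g: _accum(self, g.reshape(self.data.shape))
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def vjp(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            _accum(self, np.broadcast_to(g, self.data.shape).copy())
        out._vjp = vjp
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t, g):
    if t.requires_grad and t.grad is not None:
        t.grad += g


def _unbroadcast(g, shape):
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = Tensor(y, parents=(x,))
    out._vjp = lambda g: _accum(x, g * (1.0 - y * y))
    return out


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    out = Tensor(y, parents=(x,))
    out._vjp = lambda g: _accum(x, g * y * (1.0 - y))
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))
    out._vjp = lambda g: _accum(x, g * mask)
    return out


def exp(x: Tensor) -> Tensor:
    y = np.exp(x.data)
    out = Tensor(y, parents=(x,))
    out._vjp = lambda g: _accum(x, g * y)
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), parents=(x,))
    out._vjp = lambda g: _accum(x, g / x.data)
    return out


def concat(tensors, axis=-1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)
    out._vjp = vjp
    return out


def logsumexp(x: Tensor, axis=-1, keepdims=False) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    s = e.sum(axis=axis, keepdims=True)
    y = (m + np.log(s))
    soft = e / s
    out = Tensor(y if keepdims else np.squeeze(y, axis=axis), parents=(x,))

    def vjp(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(x, g * soft)
    out._vjp = vjp
    return out


def where_mask(mask, a: Tensor, b: Tensor) -> Tensor:
    """mask * a + (1 - mask) * b with a constant 0/1 mask array."""
    m = np.asarray(mask, dtype=np.float64)
    return a * Tensor(m) + b * Tensor(1.0 - m)


def embedding(table: Tensor, ids) -> Tensor:
    """Row lookup: table (V, E), ids int array (...,) -> (..., E)."""
    ids = np.asarray(ids)
    out = Tensor(table.data[ids], parents=(table,))

    def vjp(g):
        if table.requires_grad:
            buf = np.zeros_like(table.data)
            np.add.at(buf, ids.reshape(-1),
                      g.reshape(-1, table.data.shape[1]))
            _accum(table, buf)
    out._vjp = vjp
    return out


def conv1d_same(x: Tensor, kernel: Tensor, bias: Tensor) -> Tensor:
    """1-D convolution, stride 1, zero 'same' padding.

    x: (B, L, C_in); kernel: (K, C_in, C_out); bias: (C_out,).
    """
    B, L, Cin = x.data.shape
    K, _, Cout = kernel.data.shape
    pad = K // 2
    xp = np.zeros((B, L + 2 * pad, Cin))
    xp[:, pad:pad + L] = x.data
    y = np.zeros((B, L, Cout))
    for k in range(K):
        y += xp[:, k:k + L] @ kernel.data[k]
    y += bias.data
    out = Tensor(y, parents=(x, kernel, bias))

    def vjp(g):
        if kernel.requires_grad:
            gk = np.zeros_like(kernel.data)
            for k in range(K):
                gk[k] = np.einsum("blc,bld->cd", xp[:, k:k + L], g)
            _accum(kernel, gk)
        _accum(bias, g.sum(axis=(0, 1)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, k:k + L] += g @ kernel.data[k].T
            _accum(x, gxp[:, pad:pad + L])
    out._vjp = vjp
    return out


def transpose(x: Tensor, axes) -> Tensor:
    out = Tensor(np.transpose(x.data, axes), parents=(x,))
    inv = np.argsort(axes)
    out._vjp = lambda g: _accum(x, np.transpose(g, inv))
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam optimizer with optional stepwise learning-rate decay."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
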