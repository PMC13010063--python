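"""Minimal reverse-mode automatic differentiation over numpy float64 arrays.

The end-to-end training objective differentiates through the encoder MLP,
pairwise latent distances, adaptive kernel weights and per-patient weighted
least-squares solves.  This module provides exactly the operations that
computation graph needs: broadcast arithmetic, ``tanh``/``exp``/``log``,
reductions, ``einsum``, an index-pair gather, concatenation and batched
linear solves.  Graphs are rebuilt each optimization step; gradients are
accumulated by a topological-order backward sweep.

Conventions
-----------
* Leaves are ``Tensor`` objects with no parents; after :func:`backward`
  their ``.grad`` holds d(output)/d(leaf).
* ``maximum`` propagates gradient where the input strictly exceeds the
  clamp value (subgradient choice at the kink).
* The k-nearest-neighbour *index* selection in the training loss is done
  outside this module on detached values; only the distance values are
  differentiated.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "astensor", "backward", "add", "sub", "mul", "div", "neg",
    "power", "matmul", "tanh", "exp", "log", "tsum", "tmean", "maximum",
    "reshape", "concat", "einsum", "take_pairs", "solve_batched", "Adam",
]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("value", "grad", "parents", "_backward")

    def __init__(self, value, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.parents = parents
        self._backward = backward
        self.grad = None

    @property
    def shape(self):
        return self.value.shape

    # operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, astensor(other))

    def __radd__(self, other):
        return add(astensor(other), self)

    def __sub__(self, other):
        return sub(self, astensor(other))

    def __rsub__(self, other):
        return sub(astensor(other), self)

    def __mul__(self, other):
        return mul(self, astensor(other))

    def __rmul__(self, other):
        return mul(astensor(other), self)

    def __truediv__(self, other):
        return div(self, astensor(other))

    def __rtruediv__(self, other):
        return div(astensor(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, astensor(other))

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape})"


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise / broadcast arithmetic


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.value + b.value

    def bwd(g):
        return _unbroadcast(g, a.value.shape), _unbroadcast(g, b.value.shape)

    return Tensor(out, (a, b), bwd)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = a.value - b.value

    def bwd(g):
        return _unbroadcast(g, a.value.shape), _unbroadcast(-g, b.value.shape)

    return Tensor(out, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.value * b.value

    def bwd(g):
        return (_unbroadcast(g * b.value, a.value.shape),
                _unbroadcast(g * a.value, b.value.shape))

    return Tensor(out, (a, b), bwd)


def div(a: Tensor, b: Tensor) -> Tensor:
    out = a.value / b.value

    def bwd(g):
        return (_unbroadcast(g / b.value, a.value.shape),
                _unbroadcast(-g * a.value / b.value ** 2, b.value.shape))

    return Tensor(out, (a, b), bwd)


def neg(a: Tensor) -> Tensor:
    return Tensor(-a.value, (a,), lambda g: (-g,))


def power(a: Tensor, exponent: float) -> Tensor:
    out = a.value ** exponent

    def bwd(g):
        return (g * exponent * a.value ** (exponent - 1),)

    return Tensor(out, (a,), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    if a.value.ndim != 2 or b.value.ndim != 2:
        raise ValueError("matmul supports 2-D operands; use einsum otherwise")
    out = a.value @ b.value

    def bwd(g):
        return g @ b.value.T, a.value.T @ g

    return Tensor(out, (a, b), bwd)


def tanh(a: Tensor) -> Tensor:
    out = np.tanh(a.value)

    def bwd(g):
        return (g * (1.0 - out ** 2),)

    return Tensor(out, (a,), bwd)


def exp(a: Tensor) -> Tensor:
    out = np.exp(a.value)

    def bwd(g):
        return (g * out,)

    return Tensor(out, (a,), bwd)


def log(a: Tensor) -> Tensor:
    out = np.log(a.value)

    def bwd(g):
        return (g / a.value,)

    return Tensor(out, (a,), bwd)


def maximum(a: Tensor, clamp: float) -> Tensor:
    out = np.maximum(a.value, clamp)
    mask = (a.value > clamp).astype(np.float64)

    def bwd(g):
        return (g * mask,)

    return Tensor(out, (a,), bwd)


# ---------------------------------------------------------------------------
# reductions and shape ops


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = a.value.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.value.shape).copy(),)

    return Tensor(out, (a,), bwd)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        count = a.value.size
    else:
        count = a.value.shape[axis]
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / count)


def reshape(a: Tensor, shape) -> Tensor:
    out = a.value.reshape(shape)

    def bwd(g):
        return (g.reshape(a.value.shape),)

    return Tensor(out, (a,), bwd)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = np.concatenate([t.value for t in tensors], axis=axis)
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, tuple(tensors), bwd)


# ---------------------------------------------------------------------------
# einsum, gather, batched solve


def einsum(subscripts: str, *operands: Tensor) -> Tensor:
    """Differentiable einsum.

    Restricted to specs where every index of each operand also appears in
    the output or another operand, so each vector-Jacobian product is again
    an einsum with the output and operand subscripts swapped.
    """
    operands = [astensor(op) for op in operands]
    in_spec, out_spec = subscripts.replace(" ", "").split("->")
    in_subs = in_spec.split(",")
    if len(in_subs) != len(operands):
        raise ValueError("operand count does not match subscripts")
    for i, sub in enumerate(in_subs):
        others = out_spec + "".join(s for j, s in enumerate(in_subs) if j != i)
        if any(ch not in others for ch in sub):
            raise ValueError(f"index of operand {i} appears nowhere else: {sub}")
    out = np.einsum(subscripts, *[op.value for op in operands])

    def bwd(g):
        grads = []
        for i, sub in enumerate(in_subs):
            other_subs = [s for j, s in enumerate(in_subs) if j != i]
            other_vals = [operands[j].value for j in range(len(operands)) if j != i]
            spec = ",".join([out_spec] + other_subs) + "->" + sub
            grads.append(np.einsum(spec, g, *other_vals))
        return tuple(grads)

    return Tensor(out, tuple(operands), bwd)


def take_pairs(a: Tensor, rows: np.ndarray, cols: np.ndarray) -> Tensor:
    """Gather ``a[rows[i], cols[i]]`` for fixed (non-differentiated) indices."""
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    out = a.value[rows, cols]

    def bwd(g):
        ga = np.zeros_like(a.value)
        np.add.at(ga, (rows, cols), g)
        return (ga,)

    return Tensor(out, (a,), bwd)


def solve_batched(a: Tensor, b: Tensor) -> Tensor:
    """Solve a_i x_i = b_i for stacks a: (n, m, m), b: (n, m, 1)."""
    out = np.linalg.solve(a.value, b.value)
    at = np.swapaxes(a.value, -1, -2)

    def bwd(g):
        gb = np.linalg.solve(at, g)
        ga = -gb @ np.swapaxes(out, -1, -2)
        return ga, gb

    return Tensor(out, (a, b), bwd)


# ---------------------------------------------------------------------------
# backward pass and optimizer


def backward(root: Tensor) -> None:
    """Accumulate gradients of ``root`` (summed over entries) into leaves."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent in node.parents:
            if id(parent) not in seen:
                stack.append((parent, False))
    for node in topo:
        node.grad = None
    root.grad = np.ones_like(root.value)
    for node in reversed(topo):
        if node._backward is None or node.grad is None:
            continue
        for parent, grad in zip(node.parents, node._backward(node.grad)):
            if grad is None:
                continue
            parent.grad = grad if parent.grad is None else parent.grad + grad


class Adam:
    """Adam optimizer over a list of leaf Tensors (full-batch usage)."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
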