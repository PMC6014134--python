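"""Minimal reverse-mode automatic differentiation over numpy arrays.

The recursive composition of tree-structured LSTM cells produces a different
computation graph for every sentence, so the package carries its own small
tape-based autodiff: a :class:`Tensor` records the operation that produced it
and ``backward`` replays the tape in reverse topological order.  Only the
handful of primitives the models need are implemented (elementwise arithmetic,
matrix-vector products, concatenation, sigmoid/tanh, and a fused softmax
cross-entropy).  Everything is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "concat",
    "sigmoid",
    "tanh",
    "matvec",
    "affine",
    "softmax_cross_entropy_mean",
    "backward",
]


class Tensor:
    """A node in the computation graph.

    Parameters
    ----------
    value : ndarray
        The forward value.
    parents : tuple of Tensor
        Graph predecessors (empty for constants and parameters).
    grad_fn : callable or None
        ``grad_fn(out_grad) -> tuple of ndarray`` returning one gradient
        contribution per parent.
    requires_grad : bool
        Whether gradients should be accumulated into ``self.grad``.
    """

    __slots__ = ("value", "parents", "grad_fn", "requires_grad", "grad")

    def __init__(self, value, parents=(), grad_fn=None, requires_grad=False):
        if type(value) is not np.ndarray or value.dtype != np.float64:
            value = np.asarray(value, dtype=np.float64)
        self.value = value
        self.parents = parents
        self.grad_fn = grad_fn
        if not requires_grad:
            for p in parents:
                if p.requires_grad:
                    requires_grad = True
                    break
        self.requires_grad = requires_grad
        self.grad = None

    @property
    def shape(self):
        return self.value.shape

    def __add__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.value + other.value,
            (self, other),
            lambda g: (g, g),
        )

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.value * other.value,
            (self, other),
            lambda g: (g * other.value, g * self.value),
        )

    __rmul__ = __mul__

    def __sub__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.value - other.value,
            (self, other),
            lambda g: (g, -g),
        )

    def __neg__(self):
        return Tensor(-self.value, (self,), lambda g: (-g,))

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(value):
    """Wrap an array as a graph constant (no gradient)."""
    return Tensor(value)


def parameter(value):
    """Wrap an array as a trainable parameter (gradient accumulated)."""
    return Tensor(value, requires_grad=True)


def concat(tensors):
    """Concatenate 1-D tensors along their only axis."""
    offsets = [0]
    for t in tensors:
        offsets.append(offsets[-1] + t.value.shape[0])

    def grad_fn(g):
        return tuple(g[offsets[i]:offsets[i + 1]] for i in range(len(tensors)))

    return Tensor(np.concatenate([t.value for t in tensors]), tuple(tensors), grad_fn)


def sigmoid(x):
    # clip keeps exp() finite; gradient uses the saturated value which is
    # exact to float64 precision at the clip boundary anyway
    v = 1.0 / (1.0 + np.exp(-x.value.clip(-500, 500)))
    return Tensor(v, (x,), lambda g: (g * v * (1.0 - v),))


def tanh(x):
    v = np.tanh(x.value)
    return Tensor(v, (x,), lambda g: (g * (1.0 - v * v),))


def matvec(W, x):
    """``W @ x`` for a 2-D weight tensor and a 1-D activation tensor."""

    def grad_fn(g):
        return np.outer(g, x.value), W.value.T @ g

    return Tensor(W.value @ x.value, (W, x), grad_fn)


def affine(W, x, b):
    """Fused ``W @ x + b``; one tape node instead of two."""

    def grad_fn(g):
        return np.outer(g, x.value), W.value.T @ g, g

    return Tensor(W.value @ x.value + b.value, (W, x, b), grad_fn)


def _log_softmax(z):
    z = z - z.max()
    return z - np.log(np.exp(z).sum())


def softmax_cross_entropy_mean(logits, labels):
    """Mean softmax cross-entropy over a batch of logit tensors.

    Parameters
    ----------
    logits : sequence of Tensor
        One 1-D logit vector per instance.
    labels : sequence of int
        Gold class index per instance.

    Returns
    -------
    Tensor
        Scalar loss ``-(1/m) sum_k log softmax(logits_k)[y_k]`` computed via
        log-sum-exp for stability.
    """
    if len(logits) == 0:
        raise ValueError("cross-entropy of an empty batch is undefined")
    if len(logits) != len(labels):
        raise ValueError("logits and labels length mismatch")
    m = len(logits)
    log_ps = [_log_softmax(t.value) for t in logits]
    loss = -sum(lp[y] for lp, y in zip(log_ps, labels)) / m

    def grad_fn(g):
        grads = []
        for lp, y in zip(log_ps, labels):
            p = np.exp(lp)
            p[y] -= 1.0
            grads.append(g * p / m)
        return tuple(grads)

    return Tensor(loss, tuple(logits), grad_fn)


def backward(root):
    """Accumulate gradients of ``root`` (a scalar) into all parameters.

    Performs an iterative reverse-topological sweep; recursion-free so deep
    right-branching sentence graphs cannot hit the interpreter stack limit.
    """
    topo = []
    seen = set()
    stack = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))

    grads = {id(root): np.ones_like(root.value)}
    for node in reversed(topo):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        if node.grad_fn is not None:
            for parent, pg in zip(node.parents, node.grad_fn(g)):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] += pg
                else:
                    grads[key] = np.array(pg, dtype=np.float64, copy=True)
        if node.grad_fn is None and node.requires_grad:
            node.grad = g if node.grad is None else node.grad + g
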