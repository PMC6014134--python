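"""The child-sum binary tree-LSTM cell, forward pass, output layer, loss
and gradient checking.

For a node *j* with children states ``(h_k, c_k)``, input ``x_j`` and
tracking vector ``e_j`` (all-zero outside the SPINN), the cell computes::

    h~   = h_left + h_right
    i    = sigmoid(W_i [x_j, h~,  e_j] + b_i)
    f_k  = sigmoid(W_f [x_j, h_k, e_j] + b_f)     (one forget gate per child,
                                                   shared weights)
    o    = sigmoid(W_o [x_j, h~,  e_j] + b_o)
    u    = tanh   (W_u [x_j, h~,  e_j] + b_u)
    c    = i * drop(u) + f_left * c_left + f_right * c_right
    h    = o * tanh(c)

Leaves receive zero child states.  ``drop`` is recurrent dropout: during
training the candidate update ``u`` is multiplied by a Bernoulli(keep_p)
mask (one mask per tree, shared across its nodes); in evaluation mode it is
the identity.  Class scores are read from the root only:
``logits = W_fc h_root + b_fc`` over the six classes
[False, CPR:3, CPR:4, CPR:5, CPR:6, CPR:9].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .corpus import CLASSES
from .parsetree import BinaryParseTree

N_CLASSES = len(CLASSES)


@dataclass
class TreeLSTMParams:
    """Gate weights, biases and the output layer.

    Gate matrices map the concatenation ``[x_j | h-context | e_j]`` (size
    ``input_dim + hidden_size + tracking_size``) to ``hidden_size``.  The
    forget-gate weights are shared between the two children; only the child
    state fed in differs.
    """

    W_i: Tensor
    W_f: Tensor
    W_o: Tensor
    W_u: Tensor
    b_i: Tensor
    b_f: Tensor
    b_o: Tensor
    b_u: Tensor
    W_fc: Tensor
    b_fc: Tensor
    input_dim: int
    hidden_size: int
    tracking_size: int

    @classmethod
    def init(cls, input_dim: int, hidden_size: int,
             tracking_size: Optional[int] = None,
             n_classes: int = N_CLASSES,
             seed: int = 0, scale: float = 0.1) -> "TreeLSTMParams":
        """Seeded uniform(-scale, scale) initialization of all weights."""
        T = hidden_size if tracking_size is None else tracking_size
        rng = np.random.default_rng(seed)
        z = input_dim + hidden_size + T

        def w(*shape):
            return ad.parameter(rng.uniform(-scale, scale, shape))

        return cls(
            W_i=w(hidden_size, z), W_f=w(hidden_size, z),
            W_o=w(hidden_size, z), W_u=w(hidden_size, z),
            b_i=w(hidden_size), b_f=w(hidden_size),
            b_o=w(hidden_size), b_u=w(hidden_size),
            W_fc=w(n_classes, hidden_size), b_fc=w(n_classes),
            input_dim=input_dim, hidden_size=hidden_size, tracking_size=T,
        )

    def tensors(self) -> Dict[str, Tensor]:
        return {k: getattr(self, k) for k in
                ("W_i", "W_f", "W_o", "W_u", "b_i", "b_f", "b_o", "b_u",
                 "W_fc", "b_fc")}

    def zero_grad(self) -> None:
        for t in self.tensors().values():
            t.grad = None


@dataclass
class NodeState:
    """Hidden state and memory cell of one tree node."""

    h: Tensor
    c: Tensor


def zero_state(hidden_size: int) -> NodeState:
    z = ad.constant(np.zeros(hidden_size))
    return NodeState(h=z, c=z)


@dataclass
class DropoutSpec:
    """Recurrent dropout: mask * x in training, identity in evaluation.

    The Bernoulli(keep_p) mask is sampled per tree and shared across that
    tree's nodes (variational-dropout style).
    """

    keep_p: float = 0.5
    train_mode: bool = False
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def sample_mask(self, size: int) -> Optional[np.ndarray]:
        if not self.train_mode or self.keep_p >= 1.0:
            return None
        return (self.rng.random(size) < self.keep_p).astype(np.float64)


def cell(x_j, left: NodeState, right: NodeState, e_j,
         params: TreeLSTMParams, mask: Optional[np.ndarray] = None) -> NodeState:
    """One child-sum tree-LSTM composition step.

    ``x_j`` and ``e_j`` may be numpy arrays (treated as constants) or
    tensors; ``mask`` is the recurrent-dropout mask or None for identity.
    """
    x = x_j if isinstance(x_j, Tensor) else ad.constant(x_j)
    e = e_j if isinstance(e_j, Tensor) else ad.constant(e_j)
    h_sum = left.h + right.h
    z = ad.concat([x, h_sum, e])
    i = ad.sigmoid(ad.affine(params.W_i, z, params.b_i))
    o = ad.sigmoid(ad.affine(params.W_o, z, params.b_o))
    u = ad.tanh(ad.affine(params.W_u, z, params.b_u))
    f_l = ad.sigmoid(ad.affine(params.W_f, ad.concat([x, left.h, e]), params.b_f))
    f_r = ad.sigmoid(ad.affine(params.W_f, ad.concat([x, right.h, e]), params.b_f))
    u_d = u if mask is None else u * ad.constant(mask)
    c = i * u_d + f_l * left.c + f_r * right.c
    h = o * ad.tanh(c)
    return NodeState(h=h, c=c)


def output_logits(root: NodeState, params: TreeLSTMParams) -> Tensor:
    return ad.affine(params.W_fc, root.h, params.b_fc)


def forward(tree: BinaryParseTree,
            node_inputs: Dict[BinaryParseTree, np.ndarray],
            params: TreeLSTMParams,
            dropout: Optional[DropoutSpec] = None) -> Tensor:
    """Bottom-up recursion over the tree; class scores from the root only.

    ``node_inputs`` maps every node to its input vector (230-dim by
    default); internal-node scores are never materialized.
    """
    mask = dropout.sample_mask(params.hidden_size) if dropout is not None else None
    e = np.zeros(params.tracking_size)
    zero = zero_state(params.hidden_size)
    states: Dict[int, NodeState] = {}
    for node in tree.postorder():
        if node.is_leaf:
            states[id(node)] = cell(node_inputs[node], zero, zero, e, params, mask)
        else:
            l, r = node.children
            states[id(node)] = cell(node_inputs[node], states[id(l)],
                                    states[id(r)], e, params, mask)
    return output_logits(states[id(tree)], params)


def predict(logits) -> str:
    """Argmax class label; ties break toward the lowest class index
    (so all-equal logits predict "False")."""
    values = logits.value if isinstance(logits, Tensor) else np.asarray(logits)
    return CLASSES[int(np.argmax(values))]


def loss(logit_tensors: Sequence[Tensor], labels: Sequence[str]) -> Tensor:
    """Mean softmax cross-entropy of a batch (log-sum-exp stabilized)."""
    idx = [CLASSES.index(y) for y in labels]
    return ad.softmax_cross_entropy_mean(list(logit_tensors), idx)


def gradient_check(loss_fn, params: TreeLSTMParams, epsilon: float = 1e-5) -> float:
    """Max relative error between backprop and central finite differences.

    ``loss_fn()`` must rebuild the forward graph from the current parameter
    values (evaluation mode, so the comparison is deterministic).  The
    relative-error denominator is floored at 1e-6: central differences of an
    O(1) loss in float64 carry ~1e-11 roundoff noise, so entries whose true
    gradient is smaller than the floor are effectively compared absolutely.
    """
    params.zero_grad()
    ad.backward(loss_fn())
    max_rel = 0.0
    for name, p in params.tensors().items():
        grad = p.grad if p.grad is not None else np.zeros_like(p.value)
        it = np.nditer(p.value, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p.value[idx]
            p.value[idx] = orig + epsilon
            up = float(loss_fn().value)
            p.value[idx] = orig - epsilon
            down = float(loss_fn().value)
            p.value[idx] = orig
            numeric = (up - down) / (2 * epsilon)
            denom = max(abs(numeric) + abs(grad[idx]), 1e-6)
            max_rel = max(max_rel, abs(numeric - grad[idx]) / denom)
    return max_rel
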