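"""Stack-augmented shift-reduce executor (SPINN) with a tracking LSTM.

The executor maintains a buffer of remaining words, a stack of partial
:class:`~chemrel.treelstm.NodeState` subtrees, and a small sequential
tracking LSTM.  Before every transition the tracking LSTM reads
``[buffer-top word vector | stack-top h | stack-second h]`` (absent slots
zero-padded) and its new hidden state becomes the ``e_j`` fed to the
composition cell.  SHIFT moves the buffer head onto the stack as a leaf —
composed through the same tree-LSTM cell with zero child states, matching
the recursive model's leaf handling — and REDUCE composes the top two stack
elements (earlier-pushed element as left child).  The final stack element's
hidden state feeds the shared output layer.

Position and subtree-containment features are not used here; a node input
is the word block alone, zero-padded to the cell's input width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .parsetree import REDUCE, SHIFT, InvalidProgramError, TransitionProgram
from .treelstm import DropoutSpec, NodeState, TreeLSTMParams, cell, output_logits, zero_state


@dataclass
class TrackingParams:
    """Standard LSTM weights for the tracking layer.

    ``W`` maps ``[x_t | h_prev]`` to the four stacked gates (i, f, o, g),
    where ``x_t = [buffer-top word vector | stack_top1.h | stack_top2.h]``.
    """

    W: Tensor
    b: Tensor
    word_dim: int
    hidden_size: int       # of the composition stack states
    tracking_size: int

    @classmethod
    def init(cls, word_dim: int, hidden_size: int, tracking_size: int,
             seed: int = 0, scale: float = 0.1) -> "TrackingParams":
        rng = np.random.default_rng(seed)
        z = word_dim + 2 * hidden_size + tracking_size
        return cls(
            W=ad.parameter(rng.uniform(-scale, scale, (4 * tracking_size, z))),
            b=ad.parameter(rng.uniform(-scale, scale, 4 * tracking_size)),
            word_dim=word_dim, hidden_size=hidden_size,
            tracking_size=tracking_size,
        )

    @classmethod
    def zeros(cls, word_dim: int, hidden_size: int, tracking_size: int,
              ) -> "TrackingParams":
        """All-zero tracking weights; the tracking state then stays zero and
        the SPINN collapses onto the plain tree-LSTM."""
        z = word_dim + 2 * hidden_size + tracking_size
        return cls(W=ad.parameter(np.zeros((4 * tracking_size, z))),
                   b=ad.parameter(np.zeros(4 * tracking_size)),
                   word_dim=word_dim, hidden_size=hidden_size,
                   tracking_size=tracking_size)

    def tensors(self):
        return {"track_W": self.W, "track_b": self.b}

    def zero_grad(self) -> None:
        self.W.grad = None
        self.b.grad = None


@dataclass
class SPINNState:
    """Buffer of remaining word vectors, stack of composed states, and the
    tracking LSTM state."""

    buffer: List[np.ndarray]
    stack: List[NodeState]
    track_h: Tensor
    track_c: Tensor


def initial_state(word_vecs: Sequence[np.ndarray], tracking_size: int) -> SPINNState:
    z = ad.constant(np.zeros(tracking_size))
    return SPINNState(buffer=list(word_vecs), stack=[], track_h=z, track_c=z)


def tracking_step(state: SPINNState, tp: TrackingParams) -> Tuple[Tensor, SPINNState]:
    """One LSTM update of the tracking layer; returns ``(e_j, new state)``.

    Missing buffer/stack slots are zero-padded, so the step is defined in
    every executor configuration.
    """
    T = tp.tracking_size
    buf_top = ad.constant(state.buffer[0] if state.buffer else np.zeros(tp.word_dim))
    s1 = state.stack[-1].h if len(state.stack) >= 1 else ad.constant(np.zeros(tp.hidden_size))
    s2 = state.stack[-2].h if len(state.stack) >= 2 else ad.constant(np.zeros(tp.hidden_size))
    z = ad.concat([buf_top, s1, s2, state.track_h])
    gates = ad.affine(tp.W, z, tp.b)
    i = ad.sigmoid(_slice(gates, 0, T))
    f = ad.sigmoid(_slice(gates, T, 2 * T))
    o = ad.sigmoid(_slice(gates, 2 * T, 3 * T))
    g = ad.tanh(_slice(gates, 3 * T, 4 * T))
    c = f * state.track_c + i * g
    h = o * ad.tanh(c)
    new = SPINNState(buffer=state.buffer, stack=state.stack, track_h=h, track_c=c)
    return h, new


def _slice(t: Tensor, lo: int, hi: int) -> Tensor:
    def grad_fn(g):
        out = np.zeros_like(t.value)
        out[lo:hi] = g
        return (out,)

    return Tensor(t.value[lo:hi], (t,), grad_fn)


def _leaf_input(word_vec: np.ndarray, input_dim: int) -> np.ndarray:
    x = np.zeros(input_dim)
    x[:word_vec.shape[0]] = word_vec
    return x


def shift(state: SPINNState, e_j: Tensor, params: TreeLSTMParams,
          mask: Optional[np.ndarray] = None) -> SPINNState:
    """Move the buffer head onto the stack as a composed leaf state."""
    if not state.buffer:
        raise InvalidProgramError("SHIFT on an empty buffer")
    word = state.buffer[0]
    zero = zero_state(params.hidden_size)
    leaf_state = cell(_leaf_input(word, params.input_dim), zero, zero, e_j,
                      params, mask)
    return SPINNState(buffer=state.buffer[1:], stack=state.stack + [leaf_state],
                      track_h=state.track_h, track_c=state.track_c)


def reduce_(state: SPINNState, e_j: Tensor, params: TreeLSTMParams,
            mask: Optional[np.ndarray] = None) -> SPINNState:
    """Compose the top two stack elements into one subtree state."""
    if len(state.stack) < 2:
        raise InvalidProgramError(f"REDUCE with stack size {len(state.stack)}")
    right = state.stack[-1]
    left = state.stack[-2]
    merged = cell(np.zeros(params.input_dim), left, right, e_j, params, mask)
    return SPINNState(buffer=state.buffer, stack=state.stack[:-2] + [merged],
                      track_h=state.track_h, track_c=state.track_c)


def run(program: TransitionProgram,
        word_vecs: Sequence[np.ndarray],
        params: TreeLSTMParams,
        tracking: TrackingParams,
        dropout: Optional[DropoutSpec] = None) -> Tensor:
    """Execute a full transition program and return the root class scores.

    A tracking step precedes every transition.  Raises
    :class:`InvalidProgramError` naming the failing step for malformed
    programs.
    """
    if len(word_vecs) != len(program.buffer):
        raise ValueError("word vectors and buffer tokens misaligned")
    mask = dropout.sample_mask(params.hidden_size) if dropout is not None else None
    state = initial_state(word_vecs, tracking.tracking_size)
    for step, t in enumerate(program.transitions):
        e_j, state = tracking_step(state, tracking)
        try:
            if t == SHIFT:
                state = shift(state, e_j, params, mask)
            elif t == REDUCE:
                state = reduce_(state, e_j, params, mask)
            else:
                raise InvalidProgramError(f"unknown transition {t!r}")
        except InvalidProgramError as err:
            raise InvalidProgramError(f"step {step}: {err}") from None
    if len(state.stack) != 1 or state.buffer:
        raise InvalidProgramError(
            f"program finished with stack size {len(state.stack)} and "
            f"{len(state.buffer)} unread buffer tokens")
    return output_logits(state.stack[0], params)
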