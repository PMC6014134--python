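"""Position features, subtree-containment features, word-embedding lookup
and node-input assembly.

Every word in a candidate sentence carries two signed distances ``[d1, d2]``
to the first- and second-appearing target entity (``d = token_index -
entity_index``, so the word right before an entity has distance -1).  Each
distance maps to a fixed 10-bit thermometer code: exact columns for
|d| <= 5, shared band columns for 6-10, 11-15, 16-20 and >= 21, mirrored on
the negative side.  The subtree-containment feature marks, per tree node,
whether a target-entity token occurs among the node's leaves; the bit is
widened to a 10-vector so it is not drowned out by the 200-dimensional word
embedding.  A node's full input is ``[word(200) | position(2x10) |
subtree(10)]`` = 230 dimensions; internal nodes carry a zero word block and
zero position block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .parsetree import BinaryParseTree
from .preprocess import Vocabulary

WORD_DIM = 200
POSITION_SIZE = 10          # per distance; two distances per word
SUBTREE_SIZE = 10
NODE_INPUT_DIM = WORD_DIM + 2 * POSITION_SIZE + SUBTREE_SIZE  # 230

# 10-bit column per distance band, transcribed from the published encoding
# table: a sign bit (set for positive distances) plus a bottom-up
# thermometer that saturates at 9 ones for |d| >= 21.
_POSITIVE_COLUMNS = {
    0:  "0000000000",
    1:  "1000000001",
    2:  "1000000011",
    3:  "1000000111",
    4:  "1000001111",
    5:  "1000011111",
    "6-10":   "1000111111",
    "11-15":  "1001111111",
    "16-20":  "1011111111",
    "21-inf": "1111111111",
}
_NEGATIVE_COLUMNS = {
    -1: "0000000001",
    -2: "0000000011",
    -3: "0000000111",
    -4: "0000001111",
    -5: "0000011111",
    # the published table elides the far-negative bands; they mirror the
    # positive ones with the sign bit clear
    "-6--10":   "0000111111",
    "-11--15":  "0001111111",
    "-16--20":  "0011111111",
    "-21--inf": "0111111111",
}


def _band(d: int) -> object:
    mag = abs(d)
    if mag <= 5:
        return d
    if mag <= 10:
        lo, hi = 6, 10
    elif mag <= 15:
        lo, hi = 11, 15
    elif mag <= 20:
        lo, hi = 16, 20
    else:
        lo, hi = 21, "inf"
    return f"{lo}-{hi}" if d > 0 else f"-{lo}--{hi}"


def encode_distance(d: int) -> np.ndarray:
    """Fixed 10-length binary thermometer code for a signed distance."""
    key = _band(int(d))
    if isinstance(key, int):
        bits = _POSITIVE_COLUMNS[key] if key >= 0 else _NEGATIVE_COLUMNS[key]
    else:
        bits = _NEGATIVE_COLUMNS[key] if key.startswith("-") else _POSITIVE_COLUMNS[key]
    return np.array([float(b) for b in bits], dtype=np.float64)


def relative_distances(tokens: Sequence[str], e1_idx: int, e2_idx: int,
                       ) -> List[Tuple[int, int]]:
    """Per-token signed distances ``(t - e1_idx, t - e2_idx)``."""
    n = len(tokens)
    if not (0 <= e1_idx < n and 0 <= e2_idx < n):
        raise IndexError("entity index out of range")
    if e1_idx == e2_idx:
        raise ValueError("the two target indices must differ")
    return [(t - e1_idx, t - e2_idx) for t in range(n)]


def subtree_flags(tree: BinaryParseTree, target_tokens: Set[str],
                  ) -> Dict[BinaryParseTree, int]:
    """Bottom-up per-node bit: 1 iff a target token is among the node's
    leaves.  Internal flags are the OR of the child flags."""
    flags: Dict[BinaryParseTree, int] = {}
    for node in tree.postorder():
        if node.is_leaf:
            flags[node] = int(node.word in target_tokens)
        else:
            l, r = node.children
            flags[node] = flags[l] | flags[r]
    return flags


def subtree_vectors(tree: BinaryParseTree, target_tokens: Set[str],
                    size: int = SUBTREE_SIZE,
                    ) -> Dict[BinaryParseTree, np.ndarray]:
    """The containment bit widened to a vector: all-ones or all-zeros."""
    return {node: np.full(size, float(bit))
            for node, bit in subtree_flags(tree, target_tokens).items()}


@dataclass
class EmbeddingTable:
    """Word-embedding lookup with a single shared rare-word vector.

    The rare vector is drawn once from uniform(-0.05, 0.05) with the stored
    seed, so filtered and unknown tokens always map to the same vector,
    within a run and across runs.
    """

    vectors: Dict[str, np.ndarray]
    dim: int = WORD_DIM
    seed: int = 0
    rare_vector: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.rare_vector is None:
            rng = np.random.default_rng(self.seed)
            self.rare_vector = rng.uniform(-0.05, 0.05, self.dim)
        for tok, vec in self.vectors.items():
            if vec.shape != (self.dim,):
                raise ValueError(f"vector for {tok!r} has shape {vec.shape}, "
                                 f"expected ({self.dim},)")

    def lookup(self, token: str, vocab: Optional[Vocabulary] = None) -> np.ndarray:
        """Vector for ``token``; rare/unknown tokens (and tokens the
        vocabulary filtered) share the fixed rare vector."""
        if vocab is not None:
            token = vocab.canonical(token)
            if token == vocab.rare_token:
                return self.rare_vector
        return self.vectors.get(token, self.rare_vector)

    def save(self, path) -> None:
        """Write word2vec text format: header ``count dim``, then one token
        and ``dim`` floats per line."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"{len(self.vectors)} {self.dim}\n")
            for tok in sorted(self.vectors):
                vals = " ".join(f"{v:.6f}" for v in self.vectors[tok])
                fh.write(f"{tok} {vals}\n")

    @classmethod
    def load(cls, path, seed: int = 0) -> "EmbeddingTable":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError(f"{path}: malformed word2vec header")
            count, dim = int(header[0]), int(header[1])
            vectors: Dict[str, np.ndarray] = {}
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise ValueError(f"{path}: bad line for token {parts[0]!r}")
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
        if len(vectors) != count:
            raise ValueError(f"{path}: header says {count} tokens, found {len(vectors)}")
        return cls(vectors=vectors, dim=dim, seed=seed)


def assemble_node_input(word_vec: np.ndarray,
                        pos_vecs: Tuple[np.ndarray, np.ndarray],
                        subtree_vec: np.ndarray,
                        word_dim: int = WORD_DIM) -> np.ndarray:
    """Concatenate ``[word | position_1 | position_2 | subtree]``."""
    if word_vec.shape != (word_dim,):
        raise ValueError(f"word block has shape {word_vec.shape}, expected ({word_dim},)")
    for pv in pos_vecs:
        if pv.shape != (POSITION_SIZE,):
            raise ValueError(f"position block has shape {pv.shape}")
    if subtree_vec.ndim != 1 or subtree_vec.shape[0] < 1:
        raise ValueError(f"subtree block has shape {subtree_vec.shape}")
    return np.concatenate([word_vec, pos_vecs[0], pos_vecs[1], subtree_vec])


def instance_node_inputs(tree: BinaryParseTree,
                         tokens: Sequence[str],
                         e1_idx: int, e2_idx: int,
                         table: EmbeddingTable,
                         vocab: Optional[Vocabulary] = None,
                         use_features: bool = True,
                         subtree_size: int = SUBTREE_SIZE,
                         ) -> Dict[BinaryParseTree, np.ndarray]:
    """Full 230-dim input per tree node for one candidate instance.

    Leaves get their word vector plus the two position codes; internal
    nodes get zero word and position blocks.  The subtree block is filled
    for every node when ``use_features`` is on (as in the tree-LSTM) and
    zeroed otherwise (as in the SPINN, which uses word vectors only).
    """
    leaves = tree.leaves()
    if [l.word for l in leaves] != list(tokens):
        raise ValueError("tree leaves do not match instance tokens")
    zero_word = np.zeros(table.dim)
    zero_pos = np.zeros(POSITION_SIZE)
    zero_sub = np.zeros(subtree_size)
    if use_features:
        dists = relative_distances(tokens, e1_idx, e2_idx)
        targets = {tokens[e1_idx], tokens[e2_idx]}
        sub = subtree_vectors(tree, targets, size=subtree_size)
    leaf_index = {id(l): i for i, l in enumerate(leaves)}
    out: Dict[BinaryParseTree, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            i = leaf_index[id(node)]
            word = table.lookup(tokens[i], vocab)
            if use_features:
                d1, d2 = dists[i]
                pos = (encode_distance(d1), encode_distance(d2))
                s = sub[node]
            else:
                pos, s = (zero_pos, zero_pos), zero_sub
            out[node] = assemble_node_input(word, pos, s, word_dim=table.dim)
        else:
            s = sub[node] if use_features else zero_sub
            out[node] = assemble_node_input(zero_word, (zero_pos, zero_pos), s,
                                            word_dim=table.dim)
    return out
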