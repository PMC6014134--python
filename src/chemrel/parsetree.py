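"""Binary constituency trees, S-expression I/O, right-branching
binarization, and conversion between trees and shift-reduce transition
programs.

Trees arrive as bracketed S-expressions, one per candidate instance, in the
dialect ``(BC6ENT1 (is (an inhibitor) (of BC6ENT2)))``: an atom is a leaf,
a two-element group is an internal node, and a three-element group whose
head is an atom is a labelled internal node.  Constituent labels are kept on
read but the models consume only words and structure.

A binary tree with ``n`` leaves linearizes to a transition program of
exactly ``n`` SHIFTs (one per leaf, left to right) and ``n - 1`` REDUCEs
(one per internal node, emitted once both children are complete); executing
the program rebuilds the tree shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Sequence, Tuple

SHIFT = "shift"
REDUCE = "reduce"


class ParseError(ValueError):
    """Malformed S-expression input."""


class InvalidProgramError(ValueError):
    """A transition program that underflows the stack or leaves residue."""


@dataclass(eq=False)
class BinaryParseTree:
    """A node with 0 or 2 children; leaves carry a word."""

    label: Optional[str] = None
    word: Optional[str] = None
    children: Tuple["BinaryParseTree", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List["BinaryParseTree"]:
        out, stack = [], [self]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    def tokens(self) -> List[str]:
        return [leaf.word for leaf in self.leaves()]

    def postorder(self) -> List["BinaryParseTree"]:
        """Children-before-parent node ordering (iterative)."""
        out, stack = [], [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                out.append(node)
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))
        return out

    def n_nodes(self) -> int:
        return len(self.postorder())

    def validate(self) -> None:
        for node in self.postorder():
            if len(node.children) not in (0, 2):
                raise ParseError(
                    f"node has {len(node.children)} children; binary trees "
                    "allow exactly 0 or 2")
            if node.is_leaf and node.word is None:
                raise ParseError("leaf without a word")


def leaf(word: str, label: Optional[str] = None) -> BinaryParseTree:
    return BinaryParseTree(label=label, word=word)


def branch(left: BinaryParseTree, right: BinaryParseTree,
           label: Optional[str] = None) -> BinaryParseTree:
    return BinaryParseTree(label=label, children=(left, right))


def _lex(text: str) -> Iterator[Tuple[str, int]]:
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "()":
            yield ch, i
            i += 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in "()":
                j += 1
            yield text[i:j], i
            i = j


def read_sexpr(text: str, auto_binarize: bool = True) -> BinaryParseTree:
    """Parse a bracketed S-expression into a :class:`BinaryParseTree`.

    Every atom is a leaf; a two-element group is a binary node.  Groups with
    more than two subtrees — e.g. ``(is (an inhibitor) (of BC6ENT2))``,
    where the verb leaf precedes two phrase subtrees — are folded
    right-branching by default, or rejected with :class:`ParseError` when
    ``auto_binarize`` is off.
    """
    # each stack frame is a list of already-parsed elements of an open group
    stack: List[List] = []
    result = None
    for tok, pos in _lex(text):
        if tok == "(":
            stack.append([])
        elif tok == ")":
            if not stack:
                raise ParseError(f"unbalanced ')' at position {pos}")
            group = stack.pop()
            node = _group_to_node(group, pos, auto_binarize)
            if stack:
                stack[-1].append(node)
            elif result is None:
                result = node
            else:
                raise ParseError(f"multiple top-level expressions at position {pos}")
        else:
            item = leaf(tok)
            if stack:
                stack[-1].append(item)
            elif result is None:
                result = item
            else:
                raise ParseError(f"multiple top-level expressions at position {pos}")
    if stack:
        raise ParseError(f"unbalanced '(': {len(stack)} group(s) left open")
    if result is None:
        raise ParseError("empty input")
    result.validate()
    return result


def _group_to_node(group: List[BinaryParseTree], pos: int,
                   auto_binarize: bool) -> BinaryParseTree:
    if not group:
        raise ParseError(f"empty group before position {pos}")
    if len(group) == 1:
        return group[0]
    if len(group) == 2:
        return branch(group[0], group[1])
    if auto_binarize:
        node = group[-1]
        for child in reversed(group[:-1]):
            node = branch(child, node)
        return node
    raise ParseError(
        f"node with {len(group)} children before position {pos}; "
        "binary trees require 2 (pass auto_binarize=True to fold)")


def write_sexpr(tree: BinaryParseTree) -> str:
    """Canonical bracketed form: leaves bare, internal nodes ``(L R)`` or
    ``(LABEL L R)``."""
    if tree.is_leaf:
        return tree.word
    l, r = (write_sexpr(c) for c in tree.children)
    if tree.label:
        return f"({tree.label} {l} {r})"
    return f"({l} {r})"


def binarize_right(tree: BinaryParseTree) -> BinaryParseTree:
    """Fold any node with >2 children into a right-branching binary node,
    preserving leaf order.  Already-binary trees pass through unchanged in
    shape."""
    if tree.is_leaf:
        return tree
    children = [binarize_right(c) for c in tree.children]
    node = children[-1]
    for child in reversed(children[:-1]):
        node = branch(child, node)
    node.label = tree.label
    return node


def right_branching_tree(tokens: Sequence[str]) -> BinaryParseTree:
    """Right-branching binary tree over a token sequence; the fallback used
    when no constituency parse is available (e.g. synthetic corpora)."""
    if not tokens:
        raise ValueError("cannot build a tree over zero tokens")
    node = leaf(tokens[-1])
    for tok in reversed(tokens[:-1]):
        node = branch(leaf(tok), node)
    return node


@dataclass(frozen=True)
class TransitionProgram:
    """A token buffer plus the SHIFT/REDUCE sequence that rebuilds a tree."""

    buffer: Tuple[str, ...]
    transitions: Tuple[str, ...]

    def validate(self) -> None:
        n_shift = sum(1 for t in self.transitions if t == SHIFT)
        n_reduce = len(self.transitions) - n_shift
        if n_shift != len(self.buffer):
            raise InvalidProgramError(
                f"{n_shift} SHIFTs for {len(self.buffer)} buffer tokens")
        if n_reduce != len(self.buffer) - 1:
            raise InvalidProgramError(
                f"{n_reduce} REDUCEs for {len(self.buffer)} tokens; need "
                f"{len(self.buffer) - 1}")
        depth = 0
        for i, t in enumerate(self.transitions):
            depth += 1 if t == SHIFT else -1
            if depth < 1:
                raise InvalidProgramError(f"stack underflow at step {i}")
        if depth != 1:
            raise InvalidProgramError(f"program ends with stack size {depth}")


def to_transitions(tree: BinaryParseTree) -> TransitionProgram:
    """Post-order linearization: SHIFT at each leaf, REDUCE at each internal
    node once both children are complete."""
    tree.validate()
    buffer, transitions = [], []
    for node in tree.postorder():
        if node.is_leaf:
            buffer.append(node.word)
            transitions.append(SHIFT)
        else:
            transitions.append(REDUCE)
    program = TransitionProgram(tuple(buffer), tuple(transitions))
    program.validate()
    return program


def from_transitions(program: TransitionProgram) -> BinaryParseTree:
    """Execute a transition program, rebuilding the tree shape.

    REDUCE pops the top two stack elements; the earlier-pushed one becomes
    the left child.  Underflow or leftover stack items raise
    :class:`InvalidProgramError`.
    """
    stack: List[BinaryParseTree] = []
    buf = list(program.buffer)
    pos = 0
    for i, t in enumerate(program.transitions):
        if t == SHIFT:
            if pos >= len(buf):
                raise InvalidProgramError(f"SHIFT on empty buffer at step {i}")
            stack.append(leaf(buf[pos]))
            pos += 1
        elif t == REDUCE:
            if len(stack) < 2:
                raise InvalidProgramError(f"REDUCE with stack size {len(stack)} at step {i}")
            right = stack.pop()
            left = stack.pop()
            stack.append(branch(left, right))
        else:
            raise InvalidProgramError(f"unknown transition {t!r} at step {i}")
    if len(stack) != 1 or pos != len(buf):
        raise InvalidProgramError(
            f"program left stack size {len(stack)} and {len(buf) - pos} "
            "unread buffer tokens")
    return stack[0]


def same_shape(a: BinaryParseTree, b: BinaryParseTree,
               compare_words: bool = True) -> bool:
    """Structural equality ignoring labels (and optionally words)."""
    stack = [(a, b)]
    while stack:
        x, y = stack.pop()
        if x.is_leaf != y.is_leaf:
            return False
        if x.is_leaf:
            if compare_words and x.word != y.word:
                return False
        else:
            stack.extend(zip(x.children, y.children))
    return True


def read_parse_file(path) -> List[Optional[BinaryParseTree]]:
    """Read a side-car parse file: one S-expression per line, ``-`` marking
    an unparseable sentence (returned as None)."""
    trees: List[Optional[BinaryParseTree]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            trees.append(None if line == "-" else read_sexpr(line))
    return trees


def write_parse_file(path, trees: Sequence[Optional[BinaryParseTree]]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for t in trees:
            fh.write(("-" if t is None else write_sexpr(t)) + "\n")
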