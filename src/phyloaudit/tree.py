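"""Phylogenetic trees: parsing, serialization, and bipartition decomposition.

Trees are rooted containers, but every topology comparison in this package is
made on the unrooted view: the root is treated as an artifact of
serialization, and the pair of edges incident to a degree-2 root is merged
into a single edge (lengths summed) when the tree is decomposed into
bipartitions.

Edge supports are read from internal-node labels, the dialect emitted by the
common ML programs. The support *scale* is inferred once per tree (any value
greater than 1 means a percent scale in [0, 100]; otherwise a probability in
[0, 1]) and recorded on the tree so that percent and probability supports are
never silently mixed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "Node",
    "Tree",
    "Bipartition",
    "BipartitionTable",
    "NewickError",
    "parse_newick",
    "read_newick",
    "write_newick",
    "bipartition_table",
    "unrooted",
    "topology_key",
]


class NewickError(ValueError):
    """Malformed Newick input; carries the character position when known."""

    def __init__(self, message: str, pos: Optional[int] = None):
        if pos is not None:
            message = f"{message} (at position {pos})"
        super().__init__(message)
        self.pos = pos


class Node:
    """A node of a rooted tree. Leaves carry a label; edges carry the length
    and support of the branch between the node and its parent."""

    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(self, label=None, length=None, support=None):
        self.label: Optional[str] = label
        self.length: Optional[float] = length
        self.support: Optional[float] = support
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} length={self.length}>"


class Tree:
    """A rooted phylogeny with optional branch lengths and edge supports.

    Attributes
    ----------
    root : Node
    support_scale : {"percent", "probability", None}
        Scale of the edge supports, inferred at parse time or set explicitly.
    """

    def __init__(self, root: Node, support_scale: Optional[str] = None):
        self.root = root
        self.support_scale = support_scale

    # -- traversal -----------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- housekeeping --------------------------------------------------

    def validate(self) -> None:
        names = self.leaf_names()
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        if any(not n for n in names):
            raise ValueError("empty leaf label")
        for node in self.postorder():
            if node.length is not None and node.length < 0:
                raise ValueError(
                    f"negative branch length {node.length} above {node.label!r}"
                )

    def copy(self) -> "Tree":
        def _copy(node: Node) -> Node:
            new = Node(node.label, node.length, node.support)
            for child in node.children:
                new.add_child(_copy(child))
            return new

        return Tree(_copy(self.root), support_scale=self.support_scale)

    def __repr__(self):  # pragma: no cover
        return f"<Tree with {self.n_leaves} leaves>"


# ---------------------------------------------------------------------------
# Newick parsing
# ---------------------------------------------------------------------------


def _strip_comments(text: str) -> str:
    """Drop bracketed [...] comments (tolerated, never interpreted)."""
    out, depth = [], 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]":
            if depth == 0:
                raise NewickError("unbalanced ']' comment bracket")
            depth -= 1
        elif depth == 0:
            out.append(ch)
    if depth:
        raise NewickError("unterminated '[' comment")
    return "".join(out)


class _Parser:
    _SPECIALS = set("(),:;")

    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str):
        raise NewickError(msg, self.pos)

    def peek(self) -> str:
        self._skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def _skip_ws(self):
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def take(self, ch: str):
        if self.peek() != ch:
            self.error(f"expected {ch!r}")
        self.pos += 1

    def label(self) -> str:
        self._skip_ws()
        if self.peek() == "'":
            self.pos += 1
            start = self.pos
            while self.pos < len(self.text) and self.text[self.pos] != "'":
                self.pos += 1
            if self.pos >= len(self.text):
                self.error("unterminated quoted label")
            lab = self.text[start : self.pos]
            self.pos += 1
            return lab
        start = self.pos
        while (
            self.pos < len(self.text)
            and self.text[self.pos] not in self._SPECIALS
            and not self.text[self.pos].isspace()
        ):
            self.pos += 1
        return self.text[start : self.pos]

    def number(self) -> float:
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] not in self._SPECIALS:
            self.pos += 1
        token = self.text[start : self.pos].strip()
        try:
            return float(token)
        except ValueError:
            self.pos = start
            self.error(f"expected a number, got {token!r}")

    def clade(self) -> Node:
        node = Node()
        if self.peek() == "(":
            self.take("(")
            node.add_child(self.clade())
            while self.peek() == ",":
                self.take(",")
                node.add_child(self.clade())
            if self.peek() != ")":
                self.error("unbalanced parentheses: expected ')'")
            self.take(")")
            lab = self.label()
            if lab:
                node.label = lab
        else:
            lab = self.label()
            if not lab:
                self.error("expected a leaf label")
            node.label = lab
        if self.peek() == ":":
            self.take(":")
            length = self.number()
            if length < 0:
                self.error(f"negative branch length {length}")
            node.length = length
        return node

    def tree(self) -> Node:
        root = self.clade()
        if self.peek() != ";":
            self.error("expected ';' terminator")
        self.take(";")
        return root


def _interpret_internal_labels(tree: Tree) -> None:
    """Numeric internal-node labels become edge supports; infer the scale."""
    values = []
    for node in tree.postorder():
        if node.is_leaf or node.label is None or node is tree.root:
            continue
        try:
            val = float(node.label)
        except ValueError:
            continue
        node.support = val
        node.label = None
        values.append(val)
    if values:
        tree.support_scale = "percent" if max(values) > 1 else "probability"


def parse_newick(text: str) -> Tree:
    """Parse a single Newick tree.

    Internal-node labels that parse as numbers are attached as edge supports;
    the support scale (percent vs probability) is inferred from their range.
    Bracketed comments are ignored. Unbalanced parentheses, duplicate leaf
    labels, and negative branch lengths are rejected with position info.
    """
    parser = _Parser(_strip_comments(text))
    root = parser.tree()
    tree = Tree(root)
    _interpret_internal_labels(tree)
    tree.validate()
    return tree


def read_newick(path) -> list[Tree]:
    """Read one or more semicolon-terminated trees from a file."""
    with open(path) as fh:
        text = _strip_comments(fh.read())
    trees = []
    for chunk in text.split(";"):
        if chunk.strip():
            trees.append(parse_newick(chunk + ";"))
    return trees


# ---------------------------------------------------------------------------
# Newick writing
# ---------------------------------------------------------------------------


def _fmt_float(x: float) -> str:
    """Shortest decimal that round-trips to the same double."""
    if x == int(x) and abs(x) < 1e16:
        return str(int(x))
    return repr(float(x))


def _quote_if_needed(label: str) -> str:
    if any(c in label for c in "(),:;[] \t'\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree, *, include_supports: bool = True) -> str:
    """Serialize a tree so that re-parsing recovers topology, lengths
    (losslessly, shortest round-trip decimals), and supports.

    Zero-length edges are written explicitly (":0"), never dropped, so star
    reference trees survive a round trip.
    """

    def _write(node: Node) -> str:
        if node.is_leaf:
            out = _quote_if_needed(node.label)
        else:
            out = "(" + ",".join(_write(c) for c in node.children) + ")"
            if node.label is not None:
                out += _quote_if_needed(node.label)
            elif include_supports and node.support is not None and node.parent is not None:
                out += _fmt_float(node.support)
        if node.length is not None:
            out += ":" + _fmt_float(node.length)
        return out

    return _write(tree.root) + ";"


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bipartition:
    """A canonical unrooted split of the leaf set.

    ``block`` is the side that does NOT contain the lexicographically smallest
    leaf, so a split and its complement canonicalize (and hash) identically.
    """

    block: frozenset
    leaf_set: frozenset = field(compare=False, hash=False)

    @classmethod
    def from_side(cls, side, leaf_set) -> "Bipartition":
        side = frozenset(side)
        leaf_set = frozenset(leaf_set)
        if not side or side == leaf_set:
            raise ValueError("a bipartition needs two non-empty blocks")
        if not side <= leaf_set:
            raise ValueError("block is not a subset of the leaf set")
        if min(leaf_set) in side:
            side = leaf_set - side
        return cls(block=side, leaf_set=leaf_set)

    @property
    def complement(self) -> frozenset:
        return self.leaf_set - self.block

    @property
    def is_trivial(self) -> bool:
        return min(len(self.block), len(self.complement)) < 2

    def __repr__(self):  # pragma: no cover
        return f"Bipartition({sorted(self.block)} | ...)"


class BipartitionTable:
    """Mapping bipartition -> (branch length, support) for one tree."""

    def __init__(self, leaf_set: frozenset):
        self.leaf_set = frozenset(leaf_set)
        self.entries: dict[Bipartition, tuple[Optional[float], Optional[float]]] = {}

    def add(self, bipartition: Bipartition, length=None, support=None):
        if bipartition in self.entries:
            # merged root-edge pair: sum lengths, keep the available support
            old_len, old_sup = self.entries[bipartition]
            if length is not None or old_len is not None:
                length = (old_len or 0.0) + (length or 0.0)
            support = old_sup if old_sup is not None else support
        self.entries[bipartition] = (length, support)

    @property
    def nontrivial(self) -> dict:
        return {b: v for b, v in self.entries.items() if not b.is_trivial}

    @property
    def trivial(self) -> dict:
        return {b: v for b, v in self.entries.items() if b.is_trivial}

    @property
    def n_nontrivial(self) -> int:
        return len(self.nontrivial)

    @property
    def n_trivial(self) -> int:
        return len(self.trivial)

    def __contains__(self, bipartition):
        return bipartition in self.entries

    def __len__(self):
        return len(self.entries)


def unrooted(tree: Tree) -> Tree:
    """Return a copy in unrooted normal form: a degree-2 root is removed by
    merging its two edges (lengths summed), leaving a root of degree >= 3
    whenever an internal child exists."""
    out = tree.copy()
    root = out.root
    if len(root.children) == 2:
        a, b = root.children
        keep, move = (a, b) if not a.is_leaf else (b, a)
        if keep.is_leaf:
            return out  # two-leaf tree: nothing to merge
        move.length = (
            None
            if move.length is None and keep.length is None
            else (move.length or 0.0) + (keep.length or 0.0)
        )
        if move.support is None:
            move.support = keep.support
        keep.add_child(move)
        keep.parent = None
        keep.length = None
        keep.support = None
        out.root = keep
    return out


def topology_key(tree: Tree) -> tuple:
    """A canonical, rooting-invariant key for the unrooted topology: the
    sorted tuple of its nontrivial bipartitions. Equal keys == identical
    topology; tuple ordering gives the deterministic tie-break used by the
    search engine."""
    table = bipartition_table(tree)
    return tuple(sorted(tuple(sorted(b.block)) for b in table.nontrivial))


def bipartition_table(tree: Tree) -> BipartitionTable:
    """Decompose a tree into its unrooted bipartitions.

    A degree-2 root contributes a single merged entry (lengths summed over the
    two root edges). An unrooted binary tree of n leaves yields n trivial and
    n - 3 nontrivial entries.
    """
    leaf_set = frozenset(tree.leaf_names())
    table = BipartitionTable(leaf_set)
    if len(leaf_set) < 2:
        return table

    below: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))

    for node in tree.postorder():
        if node is tree.root:
            continue
        side = below[id(node)]
        if not side or side == leaf_set:
            continue
        bip = Bipartition.from_side(side, leaf_set)
        table.add(bip, node.length, node.support)
    return table
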