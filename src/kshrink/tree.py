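"""Phylogenetic tree container and Newick I/O.

Trees are stored rooted (an unrooted phylogeny gets an arbitrary degree->=2
root); every algorithm downstream is rooting-invariant. Branch lengths are
nonnegative reals in whatever units the input Newick uses. Leaf labels are
unique, non-empty strings and the lexicographic order on labels backs all
deterministic tie-breaking in the package.

Newick parsing and serialisation are delegated to dendropy; the internal
:class:`Tree`/:class:`Node` structure exists because the diameter engine
needs explicit parent pointers, ordered children and stable node identity
for its persistent per-node records.
"""

from __future__ import annotations

import re
import warnings
from typing import Callable, Iterable, Iterator

import dendropy

__all__ = [
    "Node",
    "Tree",
    "NewickError",
    "parse_newick",
    "parse_newick_file",
    "write_newick",
    "leaf_distance",
    "restrict_tree",
    "distance_matrix",
    "reroot_on_edge",
]


class NewickError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


class Node:
    """A tree node: ``length`` is the branch length to the parent (0 at the root)."""

    __slots__ = ("label", "length", "parent", "children")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.parent: Node | None = None
        self.children: list[Node] = []

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} len={self.length:g}>"


class Tree:
    """Rooted container for a (possibly conceptually unrooted) phylogeny."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        self._leaf_index: dict[str, Node] = {}
        self._reindex()

    # -- construction / bookkeeping -------------------------------------
    def _reindex(self) -> None:
        self._leaf_index.clear()
        for node in self.postorder():
            if node.is_leaf:
                label = node.label
                if not label:
                    raise NewickError("tree contains an unlabeled leaf")
                if label in self._leaf_index:
                    raise NewickError(f"duplicate leaf label: {label!r}")
                self._leaf_index[label] = node
            if node.length < 0:
                raise NewickError(
                    f"negative branch length {node.length} on node {node.label!r}"
                )

    # -- traversal ------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    # -- queries --------------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self._leaf_index)

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self._leaf_index)

    def leaf(self, label: str) -> Node:
        try:
            return self._leaf_index[label]
        except KeyError:
            raise KeyError(f"no leaf labeled {label!r} in tree") from None

    def has_leaf(self, label: str) -> bool:
        return label in self._leaf_index

    # -- copying --------------------------------------------------------
    def copy_with_map(self) -> tuple["Tree", dict[Node, Node]]:
        """Deep-copy the tree, returning the copy and an old->new node map."""
        mapping: dict[Node, Node] = {}
        for node in self.postorder():
            clone = Node(node.label, node.length)
            for child in node.children:
                clone.add_child(mapping[child])
            mapping[node] = clone
        return Tree(mapping[self.root], rooted=self.rooted), mapping

    def copy(self) -> "Tree":
        return self.copy_with_map()[0]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree n_leaves={self.n_leaves} rooted={self.rooted}>"


# ---------------------------------------------------------------------------
# Newick I/O (via dendropy)
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree, strict: bool) -> Tree:
    def convert(dnode, is_root: bool) -> Node:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        length = dnode.edge.length
        if length is None:
            if not is_root:
                if strict:
                    raise NewickError(
                        f"missing branch length on edge above {label!r} (strict mode)"
                    )
                warnings.warn(
                    f"missing branch length above node {label!r}; treated as 0",
                    stacklevel=4,
                )
            length = 0.0
        if length < 0:
            raise NewickError(f"negative branch length {length} above node {label!r}")
        node = Node(label, length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild, False))
        return node

    return Tree(convert(dtree.seed_node, True))


def parse_newick(text: str, strict: bool = False) -> Tree:
    """Parse a single Newick string into a :class:`Tree`.

    Branch lengths absent from the input are treated as 0 with a warning
    (``strict=True`` rejects them); negative lengths and duplicate leaf
    labels are always rejected. Quoted labels are supported and internal
    node labels are preserved (but ignored by every algorithm).
    """
    text = text.strip()
    if not text:
        raise NewickError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"unparseable Newick: {exc}") from exc
    return _from_dendropy(dtree, strict)


def parse_newick_file(path, strict: bool = False) -> list[Tree]:
    """Parse a Newick file; each non-empty line/tree is a separate gene tree."""
    try:
        dtrees = dendropy.TreeList.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickError(f"unparseable Newick file {path}: {exc}") from exc
    return [_from_dendropy(dt, strict) for dt in dtrees]


_UNQUOTED_SAFE = re.compile(r"^[^\s()\[\]{}/\\,;:=*'\"`<>]+$")


def _format_label(label: str) -> str:
    if _UNQUOTED_SAFE.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _format_length(length: float) -> str:
    return f"{length:.12g}"


def write_newick(tree: Tree) -> str:
    """Serialise a tree to Newick (12 significant digits on branch lengths)."""

    def fmt(node: Node, is_root: bool) -> str:
        if node.is_leaf:
            body = _format_label(node.label)
        else:
            inner = ",".join(fmt(c, False) for c in node.children)
            body = f"({inner})"
            if node.label:
                body += _format_label(node.label)
        if is_root:
            return body
        return f"{body}:{_format_length(node.length)}"

    return fmt(tree.root, True) + ";"


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def leaf_distance(tree: Tree, a: str, b: str) -> float:
    """Path-length distance between leaves ``a`` and ``b`` (sum of branch lengths)."""
    na, nb = tree.leaf(a), tree.leaf(b)
    if na is nb:
        return 0.0
    dist_a: dict[int, float] = {}
    node, d = na, 0.0
    while node is not None:
        dist_a[id(node)] = d
        d += node.length
        node = node.parent
    node, d = nb, 0.0
    while node is not None:
        if id(node) in dist_a:
            return d + dist_a[id(node)]
        d += node.length
        node = node.parent
    raise RuntimeError("leaves share no ancestor; tree is malformed")


def distance_matrix(tree: Tree):
    """All-pairs leaf distances: ``(sorted labels, dense numpy matrix)``.

    O(n^2); used by the brute-force oracles and tests.
    """
    import numpy as np

    labels = tree.leaf_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    mat = np.zeros((n, n))
    # For each node, distances from contained leaves to the node; merge children.
    below: dict[int, list[tuple[int, float]]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = [(index[node.label], 0.0)]
            continue
        merged: list[tuple[int, float]] = []
        for child in node.children:
            entry = [(i, d + child.length) for i, d in below.pop(id(child))]
            for i, di in merged:
                for j, dj in entry:
                    mat[i, j] = mat[j, i] = di + dj
            merged.extend(entry)
        below[id(node)] = merged
    return labels, mat


# ---------------------------------------------------------------------------
# Restriction
# ---------------------------------------------------------------------------

def restrict_tree(tree: Tree, labels: Iterable[str], mode: str = "drop") -> Tree:
    """Restrict a tree to a subset of its leaves.

    ``mode='drop'`` removes the given labels; ``mode='keep'`` retains exactly
    the given labels. Degree-2 internal nodes created by the pruning are
    suppressed with branch lengths summed, so pairwise distances among the
    remaining leaves are unchanged. The result must retain >= 1 leaf.
    """
    labels = set(labels)
    unknown = labels - set(tree._leaf_index)
    if unknown:
        raise KeyError(f"labels not in tree: {sorted(unknown)}")
    if mode == "drop":
        keep = set(tree._leaf_index) - labels
    elif mode == "keep":
        keep = labels
    else:
        raise ValueError(f"mode must be 'keep' or 'drop', got {mode!r}")
    if not keep:
        raise ValueError("restriction would drop every leaf")

    def prune(node: Node) -> Node | None:
        if node.is_leaf:
            if node.label in keep:
                return Node(node.label, node.length)
            return None
        kept = [c for c in (prune(child) for child in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            # suppress this now-degree-2 node: fold its branch into the child
            child = kept[0]
            child.length += node.length
            return child
        new = Node(node.label, node.length)
        for c in kept:
            new.add_child(c)
        return new

    root = prune(tree.root)
    assert root is not None
    root.length = 0.0
    root.parent = None
    return Tree(root, rooted=tree.rooted)


# ---------------------------------------------------------------------------
# Rerooting
# ---------------------------------------------------------------------------

def _suppress_unary(tree: Tree) -> Tree:
    """Collapse single-child internal nodes (merging branch lengths), in place."""

    def walk(node: Node) -> Node:
        while len(node.children) == 1 and not node.is_leaf:
            child = node.children[0]
            child.length += node.length
            node = child
        node.children = [walk(c) for c in node.children]
        for c in node.children:
            c.parent = node
        return node

    root = walk(tree.root)
    # root itself with a single child: promote the child
    while len(root.children) == 1:
        root = root.children[0]
        root.length = 0.0
    root.parent = None
    root.length = 0.0
    return Tree(root, rooted=tree.rooted)


def reroot_on_edge(
    tree: Tree, child: Node, dist_from_child: float, rooted: bool | None = None
) -> Tree:
    """Return a copy of ``tree`` rerooted on the edge above ``child``.

    The new root subdivides that edge ``dist_from_child`` away from ``child``
    (0 <= dist_from_child <= edge length). All pairwise leaf distances are
    preserved. ``child`` must be a node of ``tree`` with a parent.
    """
    if child.parent is None:
        raise ValueError("cannot reroot on the root's (nonexistent) parent edge")
    length = child.length
    if not (0.0 <= dist_from_child <= length or length == 0.0):
        raise ValueError(
            f"dist_from_child {dist_from_child} outside edge length {length}"
        )
    copy, mapping = tree.copy_with_map()
    c = mapping[child]
    p = c.parent
    p.children.remove(c)
    new_root = Node(None, 0.0)
    c.length = dist_from_child
    new_root.add_child(c)

    # reverse parent pointers from p back to the old root
    def reverse(node: Node, new_parent: Node, new_length: float) -> None:
        old_parent = node.parent
        old_length = node.length
        node.parent = None
        node.length = 0.0
        new_parent.add_child(node)
        node.length = new_length
        if old_parent is not None:
            old_parent.children.remove(node)
            reverse(old_parent, node, old_length)

    reverse(p, new_root, max(length - dist_from_child, 0.0))
    out = Tree(new_root, rooted=tree.rooted if rooted is None else rooted)
    return _suppress_unary(out)
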