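"""Diameter-pair machinery: per-node farthest-leaf records and their
maintenance under leaf removal.

Every node ``u`` of a rooted tree carries a 4-field record:

* ``far_leaf`` — the leaf below ``u`` farthest from ``u`` (ties broken by
  lexicographically smallest label),
* ``far_dist`` — its distance to ``u``,
* ``second_leaf`` — the farthest leaf below ``u`` outside the child subtree
  containing ``far_leaf`` (``None`` if no second child subtree survives),
* ``pair_dist`` — ``far_dist + dist(u, second_leaf)``, i.e. the length of the
  best leaf path passing through ``u`` (0 when ``second_leaf`` is ``None``).

The tree diameter is the maximum ``pair_dist`` over all nodes, attained at
the junction of a diameter pair. Removing a leaf only invalidates records on
that leaf's root path, so a removal rewrites those records and leaves all
others shared with the predecessor state. States are persistent: updating
never mutates the state it was derived from, which lets the k-shrink search
branch from one state many times.
"""

from __future__ import annotations

from typing import NamedTuple

from .tree import Node, Tree, reroot_on_edge

__all__ = [
    "NodeRecord",
    "LeafPair",
    "RecordState",
    "compute_records",
    "global_diameter_pair",
    "remove_leaf_update",
    "reroot_centroid",
    "tree_height_edges",
]


class NodeRecord(NamedTuple):
    far_leaf: str
    far_dist: float
    second_leaf: str | None
    pair_dist: float


class LeafPair(NamedTuple):
    """A leaf pair in canonical order (``leaf_a <= leaf_b`` lexicographically)."""

    leaf_a: str
    leaf_b: str
    distance: float


def _combine(node: Node, records: dict[Node, NodeRecord | None]) -> NodeRecord | None:
    """Record of an internal node from its children's current records.

    Children whose subtree has no surviving leaf (record ``None``) are
    ignored; returns ``None`` if no child survives.
    """
    entries: list[tuple[float, str]] = []
    for child in node.children:
        rec = records[child]
        if rec is None:
            continue
        entries.append((rec.far_dist + child.length, rec.far_leaf))
    if not entries:
        return None
    entries.sort(key=lambda e: (-e[0], e[1]))
    d1, x = entries[0]
    if len(entries) == 1:
        return NodeRecord(x, d1, None, 0.0)
    d2, y = entries[1]
    return NodeRecord(x, d1, y, d1 + d2)


class RecordState:
    """Records for a tree with a (possibly empty) set of leaves removed.

    Immutable by convention: :func:`remove_leaf_update` returns a new state
    sharing the same base tree. The base tree is never restructured; removed
    leaves are simply masked out of the records (suppressing the resulting
    degree-2 nodes would not change any leaf-to-leaf distance).
    """

    __slots__ = ("tree", "records", "removed", "n_active", "_pair")

    def __init__(
        self,
        tree: Tree,
        records: dict[Node, NodeRecord | None],
        removed: frozenset[str],
        n_active: int,
    ):
        self.tree = tree
        self.records = records
        self.removed = removed
        self.n_active = n_active
        self._pair: LeafPair | None = None

    def diameter_pair(self) -> LeafPair:
        if self._pair is None:
            self._pair = global_diameter_pair(self)
        return self._pair

    @property
    def diameter(self) -> float:
        return self.diameter_pair().distance


def compute_records(tree: Tree) -> RecordState:
    """Build all node records in one post-order pass (no leaves removed)."""
    records: dict[Node, NodeRecord | None] = {}
    for node in tree.postorder():
        if node.is_leaf:
            records[node] = NodeRecord(node.label, 0.0, None, 0.0)
        else:
            records[node] = _combine(node, records)
    return RecordState(tree, records, frozenset(), tree.n_leaves)


def global_diameter_pair(state: RecordState) -> LeafPair:
    """The diameter pair of the (restricted) tree, canonical among ties.

    Scans all records for the maximal ``pair_dist``; among nodes tied at the
    maximum, returns the lexicographically smallest sorted leaf pair.
    """
    if state.n_active < 2:
        raise ValueError("degenerate tree: fewer than 2 leaves remain")
    best = -1.0
    candidates: list[tuple[str, str]] = []
    for rec in state.records.values():
        if rec is None or rec.second_leaf is None:
            continue
        if rec.pair_dist > best:
            best = rec.pair_dist
            candidates = [(rec.far_leaf, rec.second_leaf)]
        elif rec.pair_dist == best:
            candidates.append((rec.far_leaf, rec.second_leaf))
    if not candidates:
        raise ValueError("degenerate tree: no leaf pair found")
    a, b = min(tuple(sorted(pair)) for pair in candidates)
    return LeafPair(a, b, best)


def remove_leaf_update(state: RecordState, leaf: str) -> RecordState:
    """A new state with ``leaf`` removed; the input state is untouched.

    Rewrites the records on the leaf's root path (each from its children's
    current records); all other records are shared. A subsequent
    :func:`global_diameter_pair` equals full recomputation on the restricted
    tree.
    """
    if leaf in state.removed:
        raise ValueError(f"leaf {leaf!r} already removed")
    node = state.tree.leaf(leaf)
    if state.n_active <= 2:
        raise ValueError("cannot remove leaf: fewer than 2 leaves would remain")
    records = dict(state.records)
    records[node] = None
    parent = node.parent
    while parent is not None:
        records[parent] = _combine(parent, records)
        parent = parent.parent
    return RecordState(state.tree, records, state.removed | {leaf}, state.n_active - 1)


# ---------------------------------------------------------------------------
# Centroid-edge rerooting (bounds the height h of the working tree)
# ---------------------------------------------------------------------------

def tree_height_edges(tree: Tree) -> int:
    """Height of the rooted tree in edges (max root-to-leaf edge count)."""
    depth = {tree.root: 0}
    best = 0
    for node in tree.preorder():
        if node is not tree.root:
            depth[node] = depth[node.parent] + 1
        if node.is_leaf:
            best = max(best, depth[node])
    return best


def reroot_centroid(tree: Tree) -> Tree:
    """Reroot a copy of the tree on its centroid edge.

    The centroid edge minimises the larger of the two leaf counts on its
    sides; ties are broken by the canonical (lexicographically sorted) side
    leaf sets. The new root subdivides the edge at its midpoint, so all leaf
    distances are preserved. Single-leaf trees are returned unchanged.
    """
    n = tree.n_leaves
    if n <= 1:
        return tree.copy()
    counts: dict[Node, int] = {}
    for node in tree.postorder():
        counts[node] = 1 if node.is_leaf else sum(counts[c] for c in node.children)
    best_max = None
    tied: list[Node] = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        side = counts[node]
        other = n - side
        if other == 0:
            continue  # edge above the root's single spanning subtree
        m = max(side, other)
        if best_max is None or m < best_max:
            best_max = m
            tied = [node]
        elif m == best_max:
            tied.append(node)
    if len(tied) > 1:
        # canonical tie-break on the pair of side leaf-sets
        def side_key(node: Node):
            below = sorted(_leaves_below(node))
            above = sorted(set(tree._leaf_index) - set(below))
            return tuple(sorted((tuple(below), tuple(above))))

        tied.sort(key=side_key)
    child = tied[0]
    return reroot_on_edge(tree, child, child.length / 2.0)


def _leaves_below(node: Node) -> list[str]:
    out = []
    stack = [node]
    while stack:
        cur = stack.pop()
        if cur.is_leaf:
            out.append(cur.label)
        else:
            stack.extend(cur.children)
    return out
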