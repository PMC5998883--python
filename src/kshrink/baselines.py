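"""Rooted-pruning baseline: midpoint (or outgroup) rooting followed by
root-to-tip standard-deviation filtering.

This is the classical alternative to diameter shrinking: root the gene tree,
compute each leaf's distance to the root, and flag leaves more than
``n_std`` sample standard deviations above the mean. It requires a rooting,
which is exactly what the diameter-based method avoids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .diameter import compute_records, global_diameter_pair
from .tree import Node, Tree, leaf_distance, reroot_on_edge

__all__ = ["RootToTipProfile", "midpoint_root", "outgroup_root", "root_to_tip", "rooted_prune"]

logger = logging.getLogger(__name__)


@dataclass
class RootToTipProfile:
    distances: dict[str, float]
    mean: float
    std: float  # sample (n-1 denominator) standard deviation


def _path_between_leaves(tree: Tree, a: str, b: str) -> list[Node]:
    """Node path from leaf a to leaf b (inclusive) through their junction."""
    na, nb = tree.leaf(a), tree.leaf(b)
    up_a = []
    node = na
    while node is not None:
        up_a.append(node)
        node = node.parent
    seen = {id(n): i for i, n in enumerate(up_a)}
    up_b = []
    node = nb
    while id(node) not in seen:
        up_b.append(node)
        node = node.parent
    return up_a[: seen[id(node)] + 1] + list(reversed(up_b))


def midpoint_root(tree: Tree) -> Tree:
    """Root a copy of the tree at the midpoint of a diameter path.

    The root lies at distance d/2 from each endpoint of the canonical
    diameter pair (subdividing an edge where needed), which minimises the
    maximum root-to-tip distance over all possible root placements.
    """
    if tree.n_leaves < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    pair = global_diameter_pair(compute_records(tree))
    target = pair.distance / 2.0
    path = _path_between_leaves(tree, pair.leaf_a, pair.leaf_b)
    walked = 0.0
    for prev, nxt in zip(path, path[1:]):
        if nxt is prev.parent:  # ascending: the edge belongs to `prev`
            child, length = prev, prev.length
        else:  # descending: the edge belongs to `nxt`
            child, length = nxt, nxt.length
        if walked + length >= target:
            offset = target - walked  # distance along the edge, from `prev` side
            dist_from_child = offset if child is prev else length - offset
            return reroot_on_edge(tree, child, dist_from_child, rooted=True)
        walked += length
    raise RuntimeError("midpoint beyond diameter path; inconsistent distances")


def outgroup_root(tree: Tree, outgroup: set[str]) -> Tree:
    """Root on the edge separating a monophyletic outgroup; else midpoint.

    If no edge bipartitions the leaf set into exactly ``outgroup`` versus the
    rest, the outgroup is not monophyletic in this (unrooted) tree and the
    tree is midpoint-rooted instead, with a warning.
    """
    outgroup = set(outgroup)
    missing = outgroup - set(tree.leaf_labels)
    if missing:
        raise KeyError(f"outgroup labels not in tree: {sorted(missing)}")
    all_leaves = set(tree.leaf_labels)
    below: dict[Node, set[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[node] = {node.label}
        else:
            below[node] = set().union(*(below[c] for c in node.children))
    for node in tree.preorder():
        if node.parent is None:
            continue
        if below[node] == outgroup or all_leaves - below[node] == outgroup:
            return reroot_on_edge(tree, node, node.length / 2.0, rooted=True)
    logger.warning("outgroup not monophyletic; falling back to midpoint rooting")
    return midpoint_root(tree)


def root_to_tip(tree: Tree) -> RootToTipProfile:
    """Distances from the root to every leaf, with mean and sample std."""
    dist: dict[str, float] = {}
    depth = {id(tree.root): 0.0}
    for node in tree.preorder():
        if node.parent is not None:
            depth[id(node)] = depth[id(node.parent)] + node.length
        if node.is_leaf:
            dist[node.label] = depth[id(node)]
    values = np.array(list(dist.values()))
    std = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return RootToTipProfile(distances=dist, mean=float(values.mean()), std=std)


def rooted_prune(tree: Tree, n_std: float = 3.0) -> set[str]:
    """Leaves whose root-to-tip distance exceeds ``mean + n_std * std``.

    ``tree`` must already be rooted meaningfully (midpoint or outgroup); with
    zero distance variance nothing is flagged.
    """
    if n_std <= 0:
        raise ValueError("n_std must be positive")
    if tree.n_leaves < 3:
        raise ValueError("rooted pruning needs at least 3 leaves")
    profile = root_to_tip(tree)
    if profile.std == 0.0:
        return set()
    cutoff = profile.mean + n_std * profile.std
    return {leaf for leaf, d in profile.distances.items() if d > cutoff}
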