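"""Exact solver for the k-shrink problem.

For a tree with branch lengths and a bound ``k``, find for every
``1 <= i <= k`` a set of ``i`` leaves whose removal minimises the diameter of
the restricted tree. Only removals of on-diameter leaves can shrink the
diameter, and after removing one endpoint of a diameter pair the other
endpoint stays on-diameter, so the search space can be organised as a DAG:
each node is a removing set annotated with a diameter pair of its restricted
tree, and spawns two children by removing either endpoint of that pair.
Children with identical removing sets are merged, which keeps row ``i`` at
``i + 1`` nodes on generic (singly paired) trees; restricting each node to a
single diameter pair is safe even under ties, since any pair-restricted
search space still contains an optimal removing set.

The brute-force enumerator is the test oracle and is deliberately guarded to
toy sizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

from .diameter import RecordState, compute_records, remove_leaf_update, reroot_centroid
from .tree import Tree, distance_matrix

__all__ = ["ShrinkResult", "default_k", "solve_kshrink", "brute_force_kshrink"]

logger = logging.getLogger(__name__)

_BRUTE_FORCE_MAX_LEAVES = 15


@dataclass
class ShrinkResult:
    """Optimal diameters ``d_0..d_k`` and removing sets ``R*_1..R*_k``.

    ``diameters[i]`` is the exact minimum diameter achievable by removing
    ``i`` leaves; ``optimal_sets[i-1]`` is the lexicographically smallest set
    attaining ``diameters[i]``. ``row_sizes[i-1]`` is the merged size of
    search row ``i`` (``i + 1`` on singly paired trees).
    """

    k: int
    diameters: list[float]
    optimal_sets: list[frozenset[str]] = field(default_factory=list)
    row_sizes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert len(self.diameters) == self.k + 1
        assert len(self.optimal_sets) == self.k


def default_k(n: int) -> int:
    """Default removal bound: ``floor(min(n/4, 5*sqrt(n)))``, capped at ``n - 2``.

    Grows sublinearly so large trees stay fast while keeping enough removal
    depth to expose outliers; trees with fewer than 4 leaves are refused
    (pass ``k`` explicitly for those).
    """
    if n < 4:
        raise ValueError(f"default_k requires n >= 4 leaves, got {n}")
    return min(n - 2, math.floor(min(n / 4.0, 5.0 * math.sqrt(n))))


def _canonical_set_key(labels: frozenset[str]) -> tuple[str, ...]:
    return tuple(sorted(labels))


def solve_kshrink(tree: Tree, k: int | None = None) -> ShrinkResult:
    """Solve the k-shrink problem exactly.

    The tree is rerooted on its centroid edge (bounding the working height),
    node records are computed once, and search rows are expanded with
    persistent record states. All tie-breaking is lexicographic on leaf
    labels, so the output is deterministic.
    """
    n = tree.n_leaves
    if n < 2:
        raise ValueError("k-shrink needs a tree with at least 2 leaves")
    if k is None:
        k = default_k(n)
    if not (0 <= k <= n - 2):
        raise ValueError(f"k must satisfy 0 <= k <= n - 2 = {n - 2}, got {k}")

    rooted = reroot_centroid(tree)
    root_state = compute_records(rooted)
    diameters = [root_state.diameter]
    optimal_sets: list[frozenset[str]] = []
    row_sizes: list[int] = []

    row: dict[frozenset[str], RecordState] = {frozenset(): root_state}
    for depth in range(1, k + 1):
        nxt: dict[frozenset[str], RecordState] = {}
        for removed in sorted(row, key=_canonical_set_key):
            state = row[removed]
            pair = state.diameter_pair()
            for leaf in (pair.leaf_a, pair.leaf_b):
                grown = removed | {leaf}
                if grown not in nxt:
                    nxt[grown] = remove_leaf_update(state, leaf)
        cap = 2 * (depth + 1)
        if len(nxt) > cap:
            # Reachable only under extensive branch-length ties; a
            # pair-restricted search space still holds an optimum, so keeping
            # the best-diameter nodes is safe.
            logger.warning(
                "search row %d grew to %d nodes; truncating to %d", depth, len(nxt), cap
            )
            keep = sorted(
                nxt, key=lambda s: (nxt[s].diameter, _canonical_set_key(s))
            )[:cap]
            nxt = {s: nxt[s] for s in keep}
        row = nxt
        row_sizes.append(len(row))
        best = min(state.diameter for state in row.values())
        achievers = [s for s, st in row.items() if st.diameter == best]
        diameters.append(best)
        optimal_sets.append(min(achievers, key=_canonical_set_key))

    return ShrinkResult(k=k, diameters=diameters, optimal_sets=optimal_sets, row_sizes=row_sizes)


def brute_force_kshrink(tree: Tree, k: int) -> ShrinkResult:
    """Exhaustive oracle: minimum diameters over *all* leaf subsets of each size.

    Restriction preserves pairwise distances, so the diameter of a restricted
    tree is just the max over the surviving entries of the full distance
    matrix. Guarded to n <= 15 leaves (test-only oracle).
    """
    n = tree.n_leaves
    if n > _BRUTE_FORCE_MAX_LEAVES:
        raise ValueError(
            f"brute-force oracle guarded to n <= {_BRUTE_FORCE_MAX_LEAVES}, got {n}"
        )
    if not (0 <= k <= n - 2):
        raise ValueError(f"k must satisfy 0 <= k <= n - 2 = {n - 2}, got {k}")
    labels, mat = distance_matrix(tree)
    idx = range(n)
    diameters = [float(mat.max())]
    optimal_sets: list[frozenset[str]] = []
    for i in range(1, k + 1):
        best = math.inf
        best_set: tuple[int, ...] | None = None
        for drop in combinations(idx, i):
            keep = [j for j in idx if j not in drop]
            diam = float(mat[keep][:, keep].max())
            if diam < best:
                best = diam
                best_set = drop
            elif diam == best:
                cand = tuple(sorted(labels[j] for j in drop))
                cur = tuple(sorted(labels[j] for j in best_set))
                if cand < cur:
                    best_set = drop
        diameters.append(best)
        optimal_sets.append(frozenset(labels[j] for j in best_set))
    return ShrinkResult(k=k, diameters=diameters, optimal_sets=optimal_sets)
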