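"""Seeded generator of multi-gene tree sets with controlled structure.

The generator produces the study conditions used throughout the tests:

* **homogeneous nulls** — random join topologies with i.i.d. exponential
  branch lengths (continuous draws make trees singly paired almost surely);
* **sporadic planted outliers** — a designated species' pendant edge is
  multiplied by a factor ``f`` in designated genes only, the tree-level
  analogue of an erroneous sequence inflating its terminal branch;
* **a rate-inflated clade** — one clade whose edges (including its stem) are
  multiplied by a rate factor in *every* gene, emulating an outgroup or a
  lineage with elevated evolutionary tempo that legitimately dominates the
  diameter and must not be over-filtered;
* **patchy occupancy** — each species is present in each gene independently
  with a given probability, as in real phylogenomic matrices.

Everything is driven by a single numpy generator seeded from the spec, so a
given spec reproduces byte-identical Newick output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tree import Node, Tree

__all__ = [
    "FixtureSpec",
    "FixtureTruth",
    "species_labels",
    "random_tree",
    "generate_tree_set",
    "plant_outlier",
    "planted_outlier_spec",
    "clade_spec",
]


def species_labels(n: int) -> list[str]:
    return [f"S{i:03d}" for i in range(1, n + 1)]


@dataclass
class FixtureSpec:
    """Parameters of one simulated gene-tree set.

    ``outliers`` lists (species, gene index, inflation factor > 1) triples;
    ``clade`` is an optional (species set, rate multiplier) pair applied in
    every gene; ``occupancy`` is the per-species probability of presence in
    a gene. ``branch_mean`` is the exponential mean branch length in
    substitutions/site (0.1 is typical of empirical gene trees).
    """

    n_species: int
    n_genes: int
    seed: int
    branch_mean: float = 0.1
    occupancy: float = 1.0
    outliers: list[tuple[str, int, float]] = field(default_factory=list)
    clade: tuple[frozenset[str], float] | None = None

    def __post_init__(self) -> None:
        if self.n_species < 4 or self.n_genes < 1:
            raise ValueError("need n_species >= 4 and n_genes >= 1")
        if not (0.0 < self.occupancy <= 1.0):
            raise ValueError("occupancy must lie in (0, 1]")
        if self.branch_mean <= 0:
            raise ValueError("branch_mean must be positive")
        labels = set(species_labels(self.n_species))
        for species, gene, factor in self.outliers:
            if species not in labels:
                raise ValueError(f"outlier species {species!r} not among the species")
            if not (0 <= gene < self.n_genes):
                raise ValueError(f"outlier gene index {gene} out of range")
            if factor <= 1.0:
                raise ValueError("inflation factors must exceed 1")
        if self.clade is not None:
            clade_set, rate = self.clade
            if not set(clade_set) <= labels:
                raise ValueError("clade species must be a subset of the species")
            if rate <= 1.0:
                raise ValueError("clade rate multiplier must exceed 1")

    @property
    def species(self) -> list[str]:
        return species_labels(self.n_species)


@dataclass
class FixtureTruth:
    """The realized outlier plan after occupancy subsampling."""

    planted: list[tuple[str, str]]  # (species, gene id) actually planted
    clade: frozenset[str] = frozenset()

    def genes_of(self, species: str) -> set[str]:
        return {g for s, g in self.planted if s == species}


def gene_id(index: int) -> str:
    return f"gene{index:03d}"


def _random_join_tree(labels: list[str], rng: np.random.Generator, mean: float) -> Node:
    """Random sequential joins over ``labels``; every non-root edge ~ Exp(mean)."""
    lineages: list[Node] = [Node(lab) for lab in sorted(labels)]
    while len(lineages) > 1:
        i, j = rng.choice(len(lineages), size=2, replace=False)
        a, b = lineages[int(i)], lineages[int(j)]
        parent = Node(None)
        a.length = float(rng.exponential(mean))
        b.length = float(rng.exponential(mean))
        parent.add_child(a)
        parent.add_child(b)
        lineages = [x for x in lineages if x is not a and x is not b]
        lineages.append(parent)
    return lineages[0]


def random_tree(
    n_or_labels: int | list[str],
    rng: np.random.Generator | int,
    branch_mean: float = 0.1,
) -> Tree:
    """One random-join tree with i.i.d. exponential branch lengths."""
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    labels = (
        species_labels(n_or_labels) if isinstance(n_or_labels, int) else list(n_or_labels)
    )
    if len(labels) < 2:
        raise ValueError("need at least 2 leaves")
    return Tree(_random_join_tree(labels, rng, branch_mean))


def _scale_subtree(node: Node, factor: float) -> None:
    stack = [node]
    while stack:
        cur = stack.pop()
        cur.length *= factor
        stack.extend(cur.children)


def generate_tree_set(spec: FixtureSpec) -> tuple[list[tuple[str, Tree]], FixtureTruth]:
    """Generate ``n_genes`` trees and the realized outlier truth table."""
    rng = np.random.default_rng(spec.seed)
    all_species = spec.species
    clade_set: frozenset[str] = spec.clade[0] if spec.clade else frozenset()
    clade_rate = spec.clade[1] if spec.clade else 1.0
    genes: list[tuple[str, Tree]] = []
    planted: list[tuple[str, str]] = []

    for g in range(spec.n_genes):
        # occupancy draw (one uniform per species, fixed consumption order)
        draws = rng.random(spec.n_species)
        present = [s for s, u in zip(all_species, draws) if u <= spec.occupancy]
        while len(present) < 4:  # pathological low occupancy: top up at random
            absent = [s for s in all_species if s not in present]
            present.append(absent[int(rng.integers(len(absent)))])
        present_set = set(present)

        clade_here = sorted(clade_set & present_set)
        rest = sorted(present_set - clade_set)
        if len(clade_here) >= 1 and rest:
            rest_root = (
                _random_join_tree(rest, rng, spec.branch_mean)
                if len(rest) > 1
                else Node(rest[0])
            )
            if len(clade_here) > 1:
                clade_root = _random_join_tree(clade_here, rng, spec.branch_mean)
            else:
                clade_root = Node(clade_here[0])
            _scale_subtree(clade_root, clade_rate)
            root = Node(None)
            clade_root.length = float(rng.exponential(spec.branch_mean)) * clade_rate
            rest_root.length = float(rng.exponential(spec.branch_mean))
            root.add_child(clade_root)
            root.add_child(rest_root)
        else:
            root = _random_join_tree(sorted(present_set), rng, spec.branch_mean)
        tree = Tree(root)

        gid = gene_id(g)
        for species, gidx, factor in spec.outliers:
            if gidx == g and species in present_set:
                leaf = tree.leaf(species)
                leaf.length *= factor
                planted.append((species, gid))
        genes.append((gid, tree))

    return genes, FixtureTruth(planted=planted, clade=clade_set)


def plant_outlier(tree: Tree, leaf: str, factor: float) -> Tree:
    """Copy of ``tree`` with the pendant edge of ``leaf`` multiplied by ``factor``.

    ``factor = 1`` returns an (equal) copy; the leaf's distance to every
    other leaf grows by exactly ``(factor - 1)`` times its pendant length.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    copy, mapping = tree.copy_with_map()
    copy.leaf(leaf).length *= factor  # KeyError for unknown leaf
    return copy


# ---------------------------------------------------------------------------
# Canned study conditions
# ---------------------------------------------------------------------------

def planted_outlier_spec(
    seed: int,
    n_species: int = 64,
    n_genes: int = 50,
    n_outliers: int = 10,
    factor: float = 20.0,
) -> FixtureSpec:
    """Sporadic-outlier condition: ``n_outliers`` distinct (species, gene)
    pairs, one per gene, each pendant edge inflated ``factor``-fold."""
    rng = np.random.default_rng(seed)
    species = species_labels(n_species)
    picked_species = rng.choice(n_species, size=n_outliers, replace=False)
    picked_genes = rng.choice(n_genes, size=n_outliers, replace=False)
    outliers = [
        (species[int(s)], int(g), factor)
        for s, g in zip(picked_species, picked_genes)
    ]
    return FixtureSpec(
        n_species=n_species, n_genes=n_genes, seed=seed, outliers=outliers
    )


def clade_spec(
    seed: int,
    n_species: int = 64,
    n_genes: int = 50,
    clade_size: int = 4,
    clade_rate: float = 5.0,
    n_outliers: int = 10,
    factor: float = 20.0,
) -> FixtureSpec:
    """Outgroup-surrogate condition: one clade rate-inflated in every gene
    plus sporadic planted outliers among the remaining species."""
    rng = np.random.default_rng(seed)
    species = species_labels(n_species)
    clade = frozenset(species[:clade_size])
    rest_idx = np.arange(clade_size, n_species)
    picked_species = rng.choice(rest_idx, size=n_outliers, replace=False)
    picked_genes = rng.choice(n_genes, size=n_outliers, replace=False)
    outliers = [
        (species[int(s)], int(g), factor)
        for s, g in zip(picked_species, picked_genes)
    ]
    return FixtureSpec(
        n_species=n_species,
        n_genes=n_genes,
        seed=seed,
        outliers=outliers,
        clade=(clade, clade_rate),
    )
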