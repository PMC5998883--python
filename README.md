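# kshrink

Erroneous sequences — contamination, mistaken orthology, misalignment — that
survive sequence-level screening usually surface as unexpectedly **long
branches** in the inferred phylogeny. `kshrink` detects such species from the
trees themselves, without requiring a rooting: it finds the leaves that
*artificially inflate the tree diameter* (the maximum path length between any
two leaves) and flags those whose impact is statistically unexpected, in a
single tree or across a collection of gene trees. Intended users are
phylogenomics practitioners curating per-gene trees before species-tree
inference, and anyone screening a large phylogeny for outlier tips.

## The method

**The k-shrink problem.** For an unrooted tree *t* with *n* leaves and branch
lengths, and a bound *k*: for every 1 ≤ *i* ≤ *k*, find *i* leaves whose
removal minimises the diameter of the restricted tree. `kshrink` solves this
exactly. Only removals of *on-diameter* leaves (endpoints of some diameter
pair) can shrink the diameter, and after removing one endpoint of a diameter
pair the other endpoint remains on-diameter. The search space is therefore a
DAG whose row-*i* nodes are *i*-removing sets annotated with a diameter pair
of their restricted tree; each node spawns two children (remove either
endpoint) and identical removing sets are merged, which keeps row *i* at
*i* + 1 nodes for trees with generic branch lengths. Restricting each node to
a single diameter pair is safe even under ties — any pair-restricted search
space still contains an optimal removing set — so ties are broken
lexicographically and the output is fully deterministic. Diameter pairs are
read off per-node *farthest-leaf records* computed in one post-order pass and
maintained incrementally (and persistently) under leaf removal, after
rerooting the tree on its centroid edge to bound the working height.

**Signatures.** With optimal diameters d₀ ≥ d₁ ≥ … ≥ d_k, let
ν_i = d_{i−1}/d_i and Δ_i = ln ν_i. The **signature** of a species in a gene
is the largest Δ_i over the optimal removing sets R\*_i containing it — its
diameter-impact score. Signatures are scale-free (rescaling all branch
lengths changes nothing).

**Outlier tests** (false-positive tolerance α, default 0.05):

* **per-gene** — fit a log-normal to one tree's signatures; flag values with
  CDF above 1 − α. Works on a single tree.
* **all-gene** — pool signatures of all genes, estimate a Gaussian kernel
  density (Silverman's rule-of-thumb bandwidth, as in R's `bw.nrd0`), flag
  above the pooled 1 − α quantile.
* **per-species** — learn a distribution *per species* across genes (zero
  imputed where a species has no signature) and flag it only in genes where
  it exceeds its *own* 1 − α quantile. This protects outgroups and
  fast-evolving clades, which legitimately dominate the diameter in every
  gene, from being over-filtered — the recommended mode for multi-gene
  datasets.

The default removal bound is k = min(n/4, 5√n), sublinear so large trees
stay fast; α and k are the only tuning knobs.

## Worked example

Simulate 30 gene trees on 24 species with two planted outliers (a pendant
edge multiplied 20-fold in one gene each), then screen them:

```bash
$ kshrink simulate --n-species 24 --n-genes 30 --seed 42 --outliers 2 --factor 20 -o trees
30 trees written to trees (seed=42, 2 planted outliers)
$ cat trees/truth.tsv
species gene
S003    gene012
S019    gene029
$ kshrink run trees/gene*.nwk -o results -a 0.05
30 gene(s) analyzed (per-species test, alpha=0.05); 28 species-gene flags -> results
$ cat results/gene012_removed.txt
species signature   threshold   test_mode
S003    1.09125     0.22846     per-species
S013    0.104987    0.0718596   per-species
```

The planted species S003 is flagged in exactly its planted gene: its
signature (Δ = 1.09, i.e. removing it shrinks that gene's diameter
e^1.09 ≈ 3.0-fold) towers over its own cross-gene threshold (0.23). The
remaining flags are background exceedances at rate ≈ α, the tolerated
false-positive level. Each gene also gets a `gene*_shrunk.nwk` with the
flagged leaves removed (all other pairwise distances preserved), plus
`summary.tsv` and a reproducibility `manifest.json`.

The same machinery is available as a library:

```python
from kshrink import parse_newick, solve_kshrink
tree = parse_newick("((A:1,B:1):1,(C:1,D:10):1);")
result = solve_kshrink(tree, k=2)
result.diameters      # [13.0, 4.0, 2.0]
result.optimal_sets   # [{'D'}, {'C', 'D'}]
```

A rooted-pruning baseline (`kshrink rooted-prune --nstd 3`, midpoint or
outgroup rooting plus root-to-tip standard-deviation filtering) is included
for comparison.

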