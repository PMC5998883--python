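# Methods

## Problem and model

Given an unrooted phylogeny *t* with nonnegative branch lengths and leaf set
of size *n*, the diameter is max over leaf pairs of the path-length distance
δ(a, b). The k-shrink problem asks, for every 1 ≤ i ≤ k, for an i-subset of
leaves whose removal minimises the diameter of the restricted tree (degree-2
nodes suppressed with lengths summed, so removal never perturbs the
distances among surviving leaves). The premise is that sequence errors
manifest as abnormally long terminal branches, so leaves whose removal
shrinks the diameter unexpectedly much are candidate errors; legitimate
long-branch taxa (outgroups, fast-evolving clades) must be distinguished
statistically, not algorithmically.

## Exact solver

Two structural facts drive the search:

1. Only on-diameter leaves can shrink the diameter, and after removing one
   endpoint of a diameter pair the surviving endpoint is still on-diameter.
2. A removing *set* determines the restricted tree regardless of the order
   of removals, so the search is over sets, not chains.

The search space is a DAG: the root is the intact tree; a node holding
removing set R and a diameter pair (x, y) of t restricted away from R spawns
children R ∪ {x} and R ∪ {y}; children in a row with identical sets are
merged. On *singly paired* trees (every leaf-restriction has a unique
diameter pair — almost sure under continuous branch-length distributions)
row i contains exactly i + 1 nodes, so the whole DAG up to depth k has
O(k²) nodes and its minimum-diameter node per row is the exact optimum. When
ties exist, restricting each node to one (canonically chosen) diameter pair
still leaves at least one optimal set in every row, so arbitrary—here
lexicographic—tie-breaking keeps the solver exact. The implementation
asserts a row cap of 2(i + 1) with best-diameter truncation as a safety
valve; it is unreachable for generic inputs.

Diameter pairs come from per-node records (farthest leaf below the node, its
distance, farthest leaf outside that child subtree, the implied
through-path length) computed in one post-order pass; the global diameter is
the maximal through-path over nodes. Removing a leaf invalidates records
only on its root path, so a removal rewrites those records into a fresh
state that shares everything else with its parent state. States are
persistent (never mutated) because the DAG expands several children from one
parent. The working tree is first rerooted on its centroid edge — the edge
minimising the larger side's leaf count — which bounds the height that each
update walks. Diameter queries scan all records with exact canonical
tie-breaking; at the problem sizes this package targets the O(n) scan is
faster in practice than maintaining an incremental maximum, and correctness
(update ≡ recomputation from scratch, verified against an all-pairs oracle)
is the contract, while the per-update cost is only a performance goal.

A brute-force enumerator (all subsets of each size, diameters from the full
distance matrix) is guarded to n ≤ 15 and serves as the oracle in tests;
solver and oracle agree to 1e-9 relative tolerance on hundreds of seeded
random instances. Greedy iteration of the best single removal is provably
not optimal: a randomized search over 8-leaf trees finds counterexamples
(strictly worse depth-2 diameter) within a few hundred draws.

## Signatures and tests

With optimal diameters d₀ … d_k, ν_i = d_{i−1}/d_i ≥ 1 and Δ_i = ln ν_i.
A species' signature in a gene is max{Δ_i : species ∈ R\*_i}, taken over the
*optimal* removing sets only (row members that are not optima have no ν
attached; an off-by-default reading that scans all row members is
deliberately not implemented). Natural log is a free choice: the tests are
log-base invariant. Signatures are undefined for species never entering an
optimal set; the per-species test imputes 0 there, the other tests simply
omit them.

Thresholds (all flag *strictly above*, for consistency across tests):

* **per-gene**: moment fit of a log-normal on the strictly positive
  signatures; threshold exp(μ̂ + σ̂ z₁₋α) with sample (ddof = 1) moments on
  logs. Fewer than 3 usable values or σ̂ = 0 → the test abstains rather than
  extrapolate from degenerate fits.
* **all-gene / per-species**: the 1 − α quantile of the equal-weight
  Gaussian mixture centred at the observations, bandwidth by Silverman's
  rule of thumb as implemented in R's `bw.nrd0`:
  0.9 · min(sd, IQR/1.349) · m^(−1/5), falling back to sd, then |x₁|, then 1
  when the minimum is zero. The fallback chain matters: per-species vectors
  are typically mostly zeros, so IQR = 0, and a naive formula would collapse
  the bandwidth and flag every positive value. The quantile is solved by
  bracketed root finding on the analytic mixture CDF (tolerance 1e-10 on the
  bandwidth scale) — deterministic and grid-free; plug-back accuracy is
  tested at 1e-8.

Defaults: α = 0.05, k = ⌊min(n/4, 5√n)⌋ capped at n − 2 (sublinear in n so
runtime does not grow worse than quadratically; large k would stop modelling
"outliers"). α is restricted to (0, 0.5]. Species present in fewer than
`min_occupancy` (default 2) genes are exempt from the per-species test —
one observation cannot support a distribution — and are logged. Flag sets
are monotone in α by construction. No multiple-testing correction is applied
across genes: α is a per-distribution tolerance, not a familywise rate.

The rooted-pruning baseline midpoint-roots each tree (root at distance d/2
along a canonical diameter path, which minimises the maximum root-to-tip
distance; an outgroup rooting is used instead when the supplied outgroup is
monophyletic) and flags leaves above mean + n_std · sd (sample sd) of the
root-to-tip distances, default n_std = 3.

## Synthetic data

The generator draws, per gene, a topology by uniformly random sequential
joins with i.i.d. Exponential(mean 0.1 substitutions/site) branch lengths —
continuous draws make trees singly paired almost surely, and 0.1 is a
typical terminal-branch scale in empirical gene trees (the choice is
immaterial to the statistics, which are scale-free). Optional structure:
per-species gene occupancy (independent Bernoulli); planted outliers — a
designated species' pendant edge multiplied by f (default 20) in designated
genes only, the tree-level analogue of an erroneous sequence; and a
rate-inflated clade — one clade (default 4 species) whose edges including
its stem are multiplied by a rate factor (default 5) in *every* gene, an
outgroup surrogate. A single seeded numpy generator drives everything;
identical specs reproduce byte-identical Newick.

What the generator does **not** emulate: sequence-level evolution and tree
estimation error (branch lengths are drawn, not inferred), topological
discordance structure between genes (each gene's topology is independent),
and correlated rate variation beyond the single planted clade. Passing tests
therefore demonstrate the solver's exactness and the tests' calibration and
contrast *given* trees; they do not certify behaviour under gene-tree
estimation noise.

A known property of the planted-outlier condition: multiplying an
exponential pendant by a fixed factor yields an absolute gain of
(f − 1)·ℓ with ℓ ~ Exp(mean), so a substantial minority of plants land on
short pendants and never reach the diameter at all — such plants carry no
tree-level signal and are undetectable by any diameter-based method.
Aggregate per-species sensitivity to ×20 plants measures ≈ 0.72 under these
conditions (the detectability ceiling itself is ≈ 0.6–0.7 per replicate
set), while the false-flag rate stays at ≈ α. The qualitative contrasts are
robust: the per-species test flags the rate-inflated clade in ~5% of genes
versus 20–27% for the all-gene and per-gene tests, at much higher
sensitivity to the sporadic plants.

## Numerical and design choices

* Branch lengths: missing → 0 with a warning (`--strict` rejects); negative
  rejected; zero allowed. Output at 12 significant digits; quoted labels
  supported; internal labels preserved but ignored.
* All tie-breaks (farthest-leaf choice, diameter-pair choice, optimal-set
  choice, centroid-edge choice) are lexicographic on leaf labels, making
  every pipeline output deterministic and rooting/permutation-invariant.
* Unrooted semantics: trees are stored with an arbitrary root; every
  statistic is verified rooting-invariant.
* k is capped at n − 2 so at least two leaves survive; d_i = d_{i−1}
  (ν_i = 1) is legal and simply contributes a zero Δ.
* Flagged species are removed simultaneously per gene (one-pass set
  removal), not iteratively re-tested.
* Problem sizes in the test suite (oracle sweeps at n ≤ 12 and full removal
  depth; statistical fixtures at 64 species × 50 genes × 10 replicates and
  100 null replicates of 24 × 16) were chosen to exercise every code path
  while keeping the whole suite around a quarter of a minute.

## Limitations

* Statistical power of the per-species test requires enough genes: with m
  genes the largest observation's mixture CDF is ≈ 1 − 0.5/m, so at
  α = 0.05 nothing can be flagged from fewer than ~11 genes per species —
  by design, small collections fall back to per-gene testing.
* The per-gene log-normal tail on a dozen-odd correlated signatures flags
  its own sample maximum in a nontrivial fraction of null trees (~30% of
  64-leaf nulls produce ≥ 1 flag); the per-entry rate remains ≈ α·k/n.
* Removal decisions are diameter-based only; topologically unstable (rogue)
  taxa with ordinary branch lengths are out of scope, as is re-estimating
  alignments or trees after filtering.
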