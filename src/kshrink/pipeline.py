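"""End-to-end pipeline: gene trees in, filtered trees + removal reports out.

``analyze_trees`` is the pure core (solve k-shrink per gene, build
signatures, apply the selected outlier test); ``run_files`` adds file I/O:
per gene a ``<gene>_shrunk.nwk`` (tree restricted away from the flagged
species) and ``<gene>_removed.txt``, plus ``summary.tsv`` and
``manifest.json`` sufficient to reproduce the run.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .outliers import (
    OutlierReport,
    all_gene_test,
    per_gene_report,
    per_species_test,
)
from .signatures import diameter_ratio_series, species_signatures
from .solver import ShrinkResult, default_k, solve_kshrink
from .tree import Tree, parse_newick_file, restrict_tree, write_newick

__all__ = ["AnalysisResult", "analyze_trees", "run_files"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    report: OutlierReport
    tables: dict[str, dict[str, float]]
    shrink: dict[str, ShrinkResult]
    trees: dict[str, Tree]
    skipped: list[str] = field(default_factory=list)

    def filtered_tree(self, gene: str) -> Tree:
        """The gene tree with its flagged species removed."""
        flagged = self.report.flagged(gene)
        tree = self.trees[gene]
        if not flagged:
            return tree
        return restrict_tree(tree, flagged, mode="drop")


def analyze_trees(
    genes: list[tuple[str, Tree]],
    alpha: float = 0.05,
    k: int | None = None,
    mode: str | None = None,
    min_occupancy: int = 2,
) -> AnalysisResult:
    """Run the shrink + signature + outlier-test pipeline on gene trees.

    ``mode`` defaults to per-species when >= 2 genes are given, else
    per-gene. ``k`` defaults to the sublinear formula per gene (capped at
    n - 2); genes with fewer than 4 leaves are skipped with a warning when no
    explicit ``k`` is given.
    """
    if not genes:
        raise ValueError("no gene trees given")
    if mode is None:
        mode = "per-species" if len(genes) > 1 else "per-gene"
    if mode in ("per-species", "all-gene") and len(genes) < 2:
        raise ValueError(f"{mode} mode needs >= 2 genes; use per-gene mode")

    tables: dict[str, dict[str, float]] = {}
    shrink: dict[str, ShrinkResult] = {}
    trees: dict[str, Tree] = {}
    skipped: list[str] = []
    for gid, tree in genes:
        n = tree.n_leaves
        if n < 4 and k is None:
            logger.warning("gene %s has only %d leaves; skipped", gid, n)
            skipped.append(gid)
            continue
        k_gene = default_k(n) if k is None else min(k, n - 2)
        result = solve_kshrink(tree, k_gene)
        tables[gid] = species_signatures(result, diameter_ratio_series(result))
        shrink[gid] = result
        trees[gid] = tree
    if not tables:
        raise ValueError("every gene was skipped; nothing to analyze")

    if mode == "per-gene":
        report = per_gene_report(tables, alpha)
    elif mode == "all-gene":
        report = all_gene_test(tables, alpha)
    else:
        occupancy = {gid: set(tree.leaf_labels) for gid, tree in trees.items()}
        report = per_species_test(tables, occupancy, alpha, min_occupancy)
    return AnalysisResult(
        report=report, tables=tables, shrink=shrink, trees=trees, skipped=skipped
    )


def _load_genes(paths: list[Path], strict: bool) -> list[tuple[str, Tree]]:
    genes: list[tuple[str, Tree]] = []
    for path in paths:
        trees = parse_newick_file(path, strict=strict)
        if len(trees) == 1:
            genes.append((path.stem, trees[0]))
        else:
            genes.extend((f"{path.stem}_tree_{i}", t) for i, t in enumerate(trees))
    return genes


def run_files(
    inputs: list[str | Path],
    outdir: str | Path,
    alpha: float = 0.05,
    k: int | None = None,
    mode: str | None = None,
    min_occupancy: int = 2,
    strict: bool = False,
    seed: int | None = None,
) -> AnalysisResult:
    """File-level entry point used by the CLI; writes all artifacts."""
    paths = [Path(p) for p in inputs]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = _load_genes(paths, strict)
    result = analyze_trees(
        genes, alpha=alpha, k=k, mode=mode, min_occupancy=min_occupancy
    )
    report = result.report

    summary_rows = []
    for gid in sorted(result.trees):
        tree = result.trees[gid]
        flags = sorted(report.flags.get(gid, []))
        with open(outdir / f"{gid}_shrunk.nwk", "w") as fh:
            fh.write(write_newick(result.filtered_tree(gid)) + "\n")
        with open(outdir / f"{gid}_removed.txt", "w") as fh:
            fh.write("species\tsignature\tthreshold\ttest_mode\n")
            for f in flags:
                fh.write(f"{f.species}\t{f.signature:.6g}\t{f.threshold:.6g}\t{report.mode}\n")
        summary_rows.append(
            {
                "gene": gid,
                "n_leaves": tree.n_leaves,
                "k": result.shrink[gid].k,
                "n_flagged": len(flags),
                "flagged": ",".join(f.species for f in flags),
            }
        )
    import pandas as pd

    pd.DataFrame(
        summary_rows, columns=["gene", "n_leaves", "k", "n_flagged", "flagged"]
    ).to_csv(outdir / "summary.tsv", sep="\t", index=False)

    manifest = {
        "tool": "kshrink",
        "version": __version__,
        "inputs": [str(p) for p in paths],
        "alpha": alpha,
        "k": k if k is not None else "default (min(n/4, 5*sqrt(n)))",
        "mode": report.mode,
        "min_occupancy": min_occupancy,
        "strict": strict,
        "seed": seed,
        "skipped_genes": result.skipped,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return result
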