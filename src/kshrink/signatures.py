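"""Diameter-ratio series and per-species impact signatures.

From the optimal diameters ``d_0..d_k`` of a shrink result, define
``nu_i = d_{i-1} / d_i >= 1`` (the proportional diameter reduction bought by
the i-th removal) and ``Delta_i = ln(nu_i) >= 0``. A species' *signature* in
a gene is the maximum ``Delta_i`` over the optimal removing sets ``R*_i``
that contain it; species never appearing in any optimal set have no
signature. Ratios are scale-free: multiplying every branch length by a
positive constant leaves ``nu``, ``Delta`` and all signatures unchanged.

The natural log is used throughout; the base only rescales thresholds
uniformly, so downstream outlier flags are base-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .solver import ShrinkResult, default_k, solve_kshrink
from .tree import Tree

__all__ = [
    "RatioSeries",
    "diameter_ratio_series",
    "species_signatures",
    "signatures_for_tree",
    "signature_frame",
]


@dataclass
class RatioSeries:
    """``nu[i-1] = d_{i-1}/d_i`` and ``delta = ln(nu)``, for ``i = 1..k``."""

    nu: np.ndarray
    delta: np.ndarray

    def __len__(self) -> int:
        return len(self.nu)


def diameter_ratio_series(result: ShrinkResult) -> RatioSeries:
    """Consecutive diameter ratios and their natural logs.

    Requires every ``d_i > 0`` (guaranteed for positive branch lengths with
    ``k <= n - 2``; all-zero-length degenerate inputs are rejected).
    """
    d = np.asarray(result.diameters, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter ratios undefined: non-positive diameter in series")
    nu = d[:-1] / d[1:]
    return RatioSeries(nu=nu, delta=np.log(nu))


def species_signatures(
    result: ShrinkResult, ratios: RatioSeries | None = None
) -> dict[str, float]:
    """Per-species signatures for one gene: ``max Delta_i`` over optimal sets
    containing the species. Species absent from every ``R*_i`` are absent."""
    if ratios is None:
        ratios = diameter_ratio_series(result)
    if len(ratios) != result.k:
        raise ValueError("ratio series length does not match result.k")
    signatures: dict[str, float] = {}
    for i, removing_set in enumerate(result.optimal_sets):
        delta_i = float(ratios.delta[i])
        for species in removing_set:
            if signatures.get(species, -1.0) < delta_i:
                signatures[species] = delta_i
    return signatures


def signatures_for_tree(tree: Tree, k: int | None = None) -> tuple[ShrinkResult, dict[str, float]]:
    """Convenience: solve k-shrink (default k if None) and return signatures."""
    if k is None:
        k = default_k(tree.n_leaves)
    result = solve_kshrink(tree, k)
    return result, species_signatures(result)


def signature_frame(tables: Mapping[str, Mapping[str, float]]):
    """Signature tables (gene -> species -> signature) as a tidy DataFrame."""
    import pandas as pd

    rows = [
        {"gene": gene, "species": species, "signature": sig}
        for gene in sorted(tables)
        for species, sig in sorted(tables[gene].items())
    ]
    return pd.DataFrame(rows, columns=["gene", "species", "signature"])
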