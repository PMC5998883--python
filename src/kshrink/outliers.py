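"""Statistical selection of outlier species from signature tables.

Three tests decide which signatures are *unexpectedly* large, each governed
by a false-positive tolerance ``alpha`` (default 0.05, restricted to
(0, 0.5]); a species is flagged when its signature lies strictly above the
test's threshold (the value whose distribution CDF equals ``1 - alpha``):

per-gene
    One tree suffices. A log-normal distribution is fitted to that gene's
    (strictly positive) signatures; the threshold is
    ``exp(mu + sigma * z_{1-alpha})`` with ``mu, sigma`` the mean and sample
    standard deviation of the log signatures. With fewer than 3 usable
    values, or zero variance, the test abstains (nothing flagged).

all-gene
    Signatures of all genes are pooled into one empirical distribution and a
    Gaussian kernel density estimate (Silverman's rule-of-thumb bandwidth,
    as in R's ``bw.nrd0``) supplies a single pooled threshold applied within
    every gene. Pooling increases power and lets legitimately long branches
    (e.g. outgroups) shape the null.

per-species
    Each species gets its own cross-gene signature distribution: in every
    gene containing the species where its signature is undefined, zero is
    imputed. The same KDE threshold machinery then yields a
    species-specific threshold, so consistently long lineages (outgroups,
    fast-evolving clades) are only flagged where they exceed their *own*
    typical impact. Species occurring in fewer than ``min_occupancy`` genes
    are exempt (too little data for a distribution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "TestConfig",
    "Flag",
    "OutlierReport",
    "fit_lognormal_threshold",
    "silverman_bandwidth",
    "kde_threshold",
    "per_gene_test",
    "all_gene_test",
    "per_species_test",
]

logger = logging.getLogger(__name__)

MODES = ("per-gene", "all-gene", "per-species")


def _check_alpha(alpha: float) -> None:
    if not (0.0 < alpha <= 0.5):
        raise ValueError(f"alpha must lie in (0, 0.5], got {alpha}")


@dataclass
class TestConfig:
    """Configuration shared by the three tests."""

    alpha: float = 0.05
    mode: str = "per-species"
    k_override: int | None = None
    min_occupancy: int = 2

    def __post_init__(self) -> None:
        _check_alpha(self.alpha)
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


class Flag(tuple):
    """A flagged (species, signature, threshold) triple."""

    __slots__ = ()

    def __new__(cls, species: str, signature: float, threshold: float):
        return super().__new__(cls, (species, float(signature), float(threshold)))

    species = property(lambda self: self[0])
    signature = property(lambda self: self[1])
    threshold = property(lambda self: self[2])


@dataclass
class OutlierReport:
    """Flags per gene plus the thresholds that produced them."""

    mode: str
    alpha: float
    flags: dict[str, list[Flag]] = field(default_factory=dict)
    #: pooled threshold (all-gene), per-gene thresholds (per-gene) or
    #: per-species thresholds (per-species); keys name the unit.
    thresholds: dict[str, float] = field(default_factory=dict)

    def flagged(self, gene: str) -> set[str]:
        return {f.species for f in self.flags.get(gene, [])}

    def n_flags(self) -> int:
        return sum(len(v) for v in self.flags.values())

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "gene": gene,
                "species": f.species,
                "signature": f.signature,
                "threshold": f.threshold,
                "test_mode": self.mode,
            }
            for gene in sorted(self.flags)
            for f in self.flags[gene]
        ]
        return pd.DataFrame(
            rows, columns=["gene", "species", "signature", "threshold", "test_mode"]
        )


# ---------------------------------------------------------------------------
# Distributional machinery
# ---------------------------------------------------------------------------

def fit_lognormal_threshold(
    signatures: Iterable[float], alpha: float
) -> float | None:
    """Log-normal tail threshold, or ``None`` when the test must abstain.

    Zeros (and any non-positive values) are excluded before the log
    transform; at least 3 usable values with positive log-variance are
    required, otherwise ``None`` is returned and nothing should be flagged.
    """
    _check_alpha(alpha)
    values = np.asarray([v for v in signatures if v > 0.0], dtype=float)
    if values.size < 3:
        logger.warning(
            "log-normal test abstains: only %d positive signatures", values.size
        )
        return None
    logs = np.log(values)
    sigma = float(np.std(logs, ddof=1))
    if sigma == 0.0:
        logger.warning("log-normal test abstains: zero variance in log signatures")
        return None
    mu = float(np.mean(logs))
    return float(np.exp(mu + sigma * norm.ppf(1.0 - alpha)))


def silverman_bandwidth(values: Sequence[float]) -> float:
    """Silverman rule-of-thumb bandwidth as in R's ``bw.nrd0``.

    ``0.9 * lo * m^(-1/5)`` with ``lo = min(sd, IQR/1.349)``; when that is 0
    (e.g. IQR = 0 for mostly-constant data) fall back to ``sd``, then
    ``|x_1|``, then 1 — so the bandwidth is always strictly positive. A
    final epsilon floor guards against pathological float underflow.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("bandwidth needs at least 2 values")
    sd = float(np.std(x, ddof=1))
    if sd < 1e-12 * max(1.0, float(np.max(np.abs(x)))):
        sd = 0.0  # constant data up to float noise
    q75, q25 = np.percentile(x, [75.0, 25.0])
    lo = min(sd, (q75 - q25) / 1.349)
    if lo == 0.0:
        lo = sd or abs(float(x[0])) or 1.0
    bw = 0.9 * lo * x.size ** (-0.2)
    if bw <= 0.0:
        bw = 1e-8 * max(1.0, float(np.max(np.abs(x))))
    return bw


def kde_threshold(
    values: Sequence[float], alpha: float, bandwidth: float | None = None
) -> float:
    """The ``1 - alpha`` quantile of the Gaussian kernel mixture over ``values``.

    The mixture CDF is the equal-weight average of Normal(v_j, bw^2) CDFs;
    the quantile is solved on that analytic CDF by bracketed root finding
    (deterministic, no density gridding).
    """
    _check_alpha(alpha)
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("KDE threshold needs at least 2 values")
    bw = silverman_bandwidth(x) if bandwidth is None else float(bandwidth)
    if bw <= 0:
        raise ValueError("bandwidth must be positive")

    def cdf(t: float) -> float:
        return float(np.mean(norm.cdf((t - x) / bw)))

    target = 1.0 - alpha
    lo = float(x.min()) - 10.0 * bw
    hi = float(x.max()) + 10.0 * bw
    # widen defensively; norm.cdf(+-10) is 1/0 to double precision already
    while cdf(hi) < target:  # pragma: no cover - unreachable for alpha > 1e-10
        hi += 10.0 * bw
    # tolerance on the bandwidth scale: the CDF varies over distances ~ bw
    return float(brentq(lambda t: cdf(t) - target, lo, hi, xtol=1e-10 * bw))


# ---------------------------------------------------------------------------
# The three tests
# ---------------------------------------------------------------------------

def per_gene_test(
    signatures: Mapping[str, float], alpha: float = 0.05
) -> tuple[set[str], float | None]:
    """Flag species of one gene whose signature is strictly above the fitted
    log-normal threshold. Returns ``(flagged species, threshold or None)``."""
    threshold = fit_lognormal_threshold(signatures.values(), alpha)
    if threshold is None:
        return set(), None
    return {s for s, v in signatures.items() if v > threshold}, threshold


def all_gene_test(
    tables: Mapping[str, Mapping[str, float]], alpha: float = 0.05
) -> OutlierReport:
    """Pool every gene's signatures, compute one KDE threshold, flag within
    each gene the species strictly above it."""
    _check_alpha(alpha)
    if len(tables) < 2:
        raise ValueError("all-gene test needs >= 2 genes; use the per-gene test")
    pooled = [v for table in tables.values() for v in table.values()]
    report = OutlierReport(mode="all-gene", alpha=alpha)
    if len(pooled) < 2:
        logger.warning("all-gene test abstains: fewer than 2 pooled signatures")
        return report
    threshold = kde_threshold(pooled, alpha)
    report.thresholds["pooled"] = threshold
    for gene, table in tables.items():
        flags = [
            Flag(s, v, threshold) for s, v in sorted(table.items()) if v > threshold
        ]
        if flags:
            report.flags[gene] = flags
    return report


def per_species_test(
    tables: Mapping[str, Mapping[str, float]],
    occupancy: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    min_occupancy: int = 2,
) -> OutlierReport:
    """Species-specific KDE thresholds with zero imputation.

    ``occupancy`` maps each gene to the species present in its tree; a
    species' distribution is assembled over exactly those genes (signature 0
    where undefined). Species present in fewer than ``min_occupancy`` genes
    are exempt and logged. A species absent from a gene can never be flagged
    there.
    """
    _check_alpha(alpha)
    if len(tables) < 2:
        raise ValueError("per-species test needs >= 2 genes; use the per-gene test")
    if set(tables) - set(occupancy):
        raise ValueError("occupancy must cover every gene in the signature tables")
    genes_of: dict[str, list[str]] = {}
    for gene in sorted(tables):
        for species in occupancy[gene]:
            genes_of.setdefault(species, []).append(gene)

    report = OutlierReport(mode="per-species", alpha=alpha)
    for species in sorted(genes_of):
        genes = genes_of[species]
        if len(genes) < max(2, min_occupancy):
            logger.warning(
                "species %s occurs in only %d gene(s); exempt from the per-species test",
                species,
                len(genes),
            )
            continue
        values = [tables[g].get(species, 0.0) for g in genes]
        threshold = kde_threshold(values, alpha)
        report.thresholds[species] = threshold
        for gene, value in zip(genes, values):
            if value > threshold:
                report.flags.setdefault(gene, []).append(Flag(species, value, threshold))
    for flags in report.flags.values():
        flags.sort()
    return report


def per_gene_report(
    tables: Mapping[str, Mapping[str, float]], alpha: float = 0.05
) -> OutlierReport:
    """Apply the per-gene test to every gene and assemble one report."""
    report = OutlierReport(mode="per-gene", alpha=alpha)
    for gene in sorted(tables):
        flagged, threshold = per_gene_test(tables[gene], alpha)
        if threshold is not None:
            report.thresholds[gene] = threshold
        if flagged:
            report.flags[gene] = [
                Flag(s, tables[gene][s], threshold) for s in sorted(flagged)
            ]
    return report
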