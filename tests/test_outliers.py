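"""The per-gene, all-gene and per-species outlier tests and their
distributional machinery."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from kshrink import (
    all_gene_test,
    compute_records,
    fit_lognormal_threshold,
    global_diameter_pair,
    kde_threshold,
    per_gene_report,
    per_gene_test,
    per_species_test,
    plant_outlier,
    signatures_for_tree,
    silverman_bandwidth,
)
from kshrink.outliers import TestConfig as OutlierTestConfig
from kshrink.simulate import FixtureSpec, generate_tree_set, random_tree


def signature_tables(genes, k=None):
    tables = {}
    occupancy = {}
    for gid, tree in genes:
        _, sigs = signatures_for_tree(tree, k)
        tables[gid] = sigs
        occupancy[gid] = set(tree.leaf_labels)
    return tables, occupancy


class TestConfigValidation:
    @pytest.mark.parametrize("alpha", [0.0, -0.1, 0.6, 1.0])
    def test_alpha_range(self, alpha):
        with pytest.raises(ValueError, match="alpha"):
            OutlierTestConfig(alpha=alpha)

    def test_bad_mode(self):
        with pytest.raises(ValueError, match="mode"):
            OutlierTestConfig(mode="per-taxon")


class TestLognormalThreshold:
    def test_single_spike_flagged(self):
        sigs = [0.1] * 19 + [2.0]
        threshold = fit_lognormal_threshold(sigs, 0.05)
        logs = np.log(sigs)
        expected = math.exp(logs.mean() + logs.std(ddof=1) * norm.ppf(0.95))
        assert threshold == pytest.approx(expected, rel=1e-12)
        assert [v for v in sigs if v > threshold] == [2.0]

    def test_constant_signatures_abstain(self):
        assert fit_lognormal_threshold([0.3, 0.3, 0.3, 0.3], 0.05) is None

    def test_too_few_values_abstain(self):
        assert fit_lognormal_threshold([0.5, 0.9], 0.05) is None

    def test_zeros_excluded_before_log(self):
        with_zeros = fit_lognormal_threshold([0.0, 0.0, 0.1, 0.2, 0.4], 0.05)
        without = fit_lognormal_threshold([0.1, 0.2, 0.4], 0.05)
        assert with_zeros == pytest.approx(without)

    def test_threshold_diverges_as_alpha_vanishes(self):
        sigs = [0.1, 0.2, 0.4, 0.8, 2.0]
        assert fit_lognormal_threshold(sigs, 1e-9) > 100 * max(sigs)


class TestSilvermanBandwidth:
    def test_reference_formula(self):
        # bw.nrd0: 0.9 * min(sd, IQR/1.349) * m^(-1/5)
        x = np.random.default_rng(3).normal(size=32)
        sd = np.std(x, ddof=1)
        q75, q25 = np.percentile(x, [75, 25])
        expected = 0.9 * min(sd, (q75 - q25) / 1.349) * 32 ** (-0.2)
        assert silverman_bandwidth(x) == pytest.approx(expected, rel=1e-12)

    def test_matches_independent_recomputation(self, rng):
        for _ in range(50):
            x = rng.normal(size=int(rng.integers(5, 80)))
            sd = np.std(x, ddof=1)
            iqr = np.subtract(*np.percentile(x, [75, 25]))
            lo = min(sd, iqr / 1.349) or sd or abs(x[0]) or 1.0
            assert silverman_bandwidth(x) == pytest.approx(
                0.9 * lo * len(x) ** (-0.2), rel=1e-9
            )

    def test_constant_data_positive_bandwidth(self):
        assert silverman_bandwidth([0.6] * 10) == pytest.approx(
            0.9 * 0.6 * 10 ** (-0.2)
        )
        assert silverman_bandwidth([0.0] * 10) > 0  # final fallback is 1

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="at least 2"):
            silverman_bandwidth([1.0])


class TestKdeThreshold:
    def test_single_component_closed_form(self):
        # one distinct value repeated: threshold = x0 + bw * z_{1-alpha}
        threshold = kde_threshold([2.0, 2.0], 0.05, bandwidth=0.7)
        assert threshold == pytest.approx(2.0 + 0.7 * norm.ppf(0.95), rel=1e-9)

    def test_symmetric_values_alpha_half(self):
        assert kde_threshold([-1.0, 1.0], 0.5) == pytest.approx(0.0, abs=1e-9)

    def test_plug_back_cdf(self, rng):
        """Mixture CDF at the returned threshold equals 1 - alpha."""
        for _ in range(50):
            x = rng.normal(size=int(rng.integers(3, 60)))
            alpha = float(rng.uniform(0.01, 0.5))
            bw = silverman_bandwidth(x)
            t = kde_threshold(x, alpha)
            cdf = float(np.mean(norm.cdf((t - x) / bw)))
            assert cdf == pytest.approx(1 - alpha, abs=1e-8)


class TestPerGene:
    def test_planted_on_diameter_outlier_flagged(self, rng):
        """A x20 inflation of a diameter-endpoint pendant edge is flagged."""
        tree = random_tree(64, rng)
        far_leaf = global_diameter_pair(compute_records(tree)).leaf_b
        planted = plant_outlier(tree, far_leaf, 20.0)
        _, sigs = signatures_for_tree(planted)
        flagged, threshold = per_gene_test(sigs, 0.05)
        assert far_leaf in flagged
        assert sigs[far_leaf] > threshold

    def test_homogeneous_null_rate(self):
        """Under the null, flags are rare: per-entry rate stays below 2*alpha
        and most trees have no flag at all."""
        n, flags, clean = 64, 0, 0
        reps = 60
        for seed in range(reps):
            tree = random_tree(n, np.random.default_rng(40_000 + seed))
            _, sigs = signatures_for_tree(tree)
            flagged, _ = per_gene_test(sigs, 0.05)
            flags += len(flagged)
            clean += not flagged
        assert flags / (n * reps) <= 0.1
        assert clean / reps >= 0.6

    def test_empty_table(self):
        assert per_gene_test({}, 0.05) == (set(), None)


class TestAllGene:
    def test_single_gene_rejected(self):
        with pytest.raises(ValueError, match="2 genes"):
            all_gene_test({"g0": {"A": 0.5}}, 0.05)

    def test_planted_outlier_found_in_its_gene_only(self, rng):
        spec = FixtureSpec(
            n_species=24, n_genes=20, seed=77, outliers=[("S005", 7, 25.0)]
        )
        genes, truth = generate_tree_set(spec)
        assert truth.planted == [("S005", "gene007")]
        tables, _ = signature_tables(genes)
        report = all_gene_test(tables, 0.05)
        assert "S005" in report.flagged("gene007")
        for gene in tables:
            assert "S005" not in report.flagged(gene) or gene == "gene007"

    def test_identical_homogeneous_genes_rate_bounded(self, rng):
        genes, _ = generate_tree_set(FixtureSpec(n_species=24, n_genes=30, seed=13))
        tables, _ = signature_tables(genes)
        report = all_gene_test(tables, 0.05)
        assert report.n_flags() <= 2 * 0.05 * 24 * 30


class TestPerSpecies:
    def test_spike_gene_flagged_only(self):
        """A species with near-zero signatures everywhere and one spike is
        flagged exactly in the spike gene."""
        tables = {f"g{i:02d}": {} for i in range(50)}
        species = [f"S{j:03d}" for j in range(10)]
        occupancy = {g: set(species) for g in tables}
        tables["g07"]["S000"] = 1.8
        report = per_species_test(tables, occupancy, 0.05)
        assert report.flagged("g07") == {"S000"}
        assert sum(len(v) for g, v in report.flags.items() if g != "g07") == 0

    def test_consistently_moderate_species_not_flagged(self):
        """Uniformly elevated signatures (outgroup-like) never exceed the
        species' own threshold."""
        tables = {f"g{i:02d}": {"OUT": 0.6} for i in range(40)}
        occupancy = {g: {"OUT", "A", "B"} for g in tables}
        report = per_species_test(tables, occupancy, 0.05)
        assert report.n_flags() == 0

    def test_absent_species_never_flagged(self):
        tables = {"g0": {"A": 2.0}, "g1": {"A": 0.0, "B": 0.1}}
        occupancy = {"g0": {"A", "B", "C"}, "g1": {"A", "B"}}
        report = per_species_test(tables, occupancy, 0.05)
        assert all(f.species != "C" for flags in report.flags.values() for f in flags)

    def test_low_occupancy_exempt(self):
        tables = {"g0": {"A": 5.0}, "g1": {"B": 0.1}}
        occupancy = {"g0": {"A", "B"}, "g1": {"B"}}
        report = per_species_test(tables, occupancy, 0.05, min_occupancy=2)
        assert report.flagged("g0") == set()  # A occurs in g0 only: exempt

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError, match="2 genes"):
            per_species_test({"g0": {}}, {"g0": set()}, 0.05)


class TestAlphaMonotonicity:
    def test_flag_sets_nest_in_alpha(self):
        """Every test flags a subset at smaller alpha (0.005 vs 0.1)."""
        spec = FixtureSpec(
            n_species=24,
            n_genes=20,
            seed=99,
            outliers=[("S003", 2, 25.0), ("S010", 11, 25.0)],
        )
        genes, _ = generate_tree_set(spec)
        tables, occupancy = signature_tables(genes)
        for build in (
            lambda a: per_gene_report(tables, a),
            lambda a: all_gene_test(tables, a),
            lambda a: per_species_test(tables, occupancy, a),
        ):
            strict_report = build(0.005)
            loose_report = build(0.1)
            for gene in tables:
                assert strict_report.flagged(gene) <= loose_report.flagged(gene)
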