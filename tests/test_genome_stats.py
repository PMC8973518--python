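"""Chromosome statistics, loop lengths, TSS profiles, annotation, joins."""

import numpy as np
import pandas as pd
import pytest

from marseq.genome_stats import (
    GeneModel,
    chromosome_summary,
    classify_context,
    density_correlation,
    gene_flank_report,
    loop_lengths,
    pathway_join,
    round_half_up,
    tss_profile,
)
from marseq.intervals import GenomicInterval, IntervalSet
from marseq.synthetic import (
    SyntheticConfig,
    make_gene_models,
    make_peak_sets,
    make_uniform_peaks,
    plant_context_peaks,
    plant_tss_peaks,
)

from oracles import pearson_oracle


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def uniform_set(chrom, n, spacing, length=100, label="t"):
    return IntervalSet(
        label, [iv(chrom, i * spacing, i * spacing + length) for i in range(n)]
    )


class TestChromosomeSummary:
    def test_density_arithmetic_matches_published_style_rows(self):
        # 20.66 Mb chromosome with 710 genes and 454 MARs: densities to two
        # decimals (half away from zero) are 34.37 genes/Mb and 21.97 MARs/Mb
        sizes = {"chr1": 20_660_000}
        mars = uniform_set("chr1", 454, 40_000, label="SG7")
        df = chromosome_summary(mars, sizes, {"chr1": 710})
        row = df.iloc[0]
        assert row["gene_density"] == 34.37
        assert row["mar_density"] == 21.97
        assert row["mar_count"] == 454

    def test_zero_mars_gives_zero_density_and_missing_loop(self):
        df = chromosome_summary(IntervalSet("t", []), {"chr1": 10_000_000}, {"chr1": 5})
        row = df.iloc[0]
        assert row["mar_density"] == 0.0
        assert np.isnan(row["mean_loop_kb"])

    def test_strict_mode_errors_on_unknown_chromosome(self):
        mars = IntervalSet("t", [iv("scaffold7", 0, 100)])
        with pytest.raises(KeyError, match="scaffold7"):
            chromosome_summary(mars, {"chr1": 1_000_000})

    def test_lenient_mode_pools_unplaced_and_conserves_totals(self):
        mars = IntervalSet(
            "t", [iv("chr1", 0, 100), iv("scaffold7", 0, 100), iv("scaffold8", 5, 60)]
        )
        df = chromosome_summary(mars, {"chr1": 1_000_000}, strict=False)
        assert df.loc[df["chrom"] == "unplaced", "mar_count"].item() == 2
        assert df["mar_count"].sum() == 3

    def test_density_increases_when_mars_added(self):
        sizes = {"chr1": 1_000_000}
        d1 = chromosome_summary(uniform_set("chr1", 5, 1000), sizes).iloc[0]
        d2 = chromosome_summary(uniform_set("chr1", 9, 1000), sizes).iloc[0]
        assert d2["mar_density_raw"] > d1["mar_density_raw"]

    def test_rounding_half_away_from_zero(self):
        assert round_half_up(1.234) == 1.23
        assert round_half_up(1.236) == 1.24
        assert round_half_up(0.125) == 0.13  # exact half rounds away from zero
        assert round_half_up(-0.125) == -0.13


class TestLoopLengths:
    def test_uniform_spacing_midpoint(self):
        mars = IntervalSet(
            "t", [iv("chr1", 0, 100), iv("chr1", 200, 300), iv("chr1", 400, 500)]
        )
        per_chrom, overall = loop_lengths(mars)
        assert per_chrom["chr1"] == pytest.approx(0.2)  # 200 bp
        assert overall == pytest.approx(0.2)

    def test_single_mar_chromosome_contributes_nothing(self):
        mars = IntervalSet("t", [iv("chr1", 0, 100)])
        per_chrom, overall = loop_lengths(mars)
        assert per_chrom.empty and np.isnan(overall)

    def test_gap_method(self):
        mars = IntervalSet("t", [iv("chr1", 0, 100), iv("chr1", 200, 300)])
        _, overall = loop_lengths(mars, method="gap")
        assert overall == pytest.approx(0.1)  # 100 bp gap

    def test_planted_uniform_peaks_recovered_exactly(self):
        peaks = make_uniform_peaks(100, 50_000, chrom_size=5_100_000)
        per_chrom, overall = loop_lengths(peaks)
        assert overall == pytest.approx(50.0)
        # uniform spacing: span/(n-1) segments equals the planted spacing
        assert per_chrom["chr1"] == pytest.approx(50.0)

    def test_aggregation_modes_differ_on_unbalanced_chromosomes(self):
        mars = IntervalSet(
            "t",
            [iv("chr1", i * 1000, i * 1000 + 100) for i in range(11)]
            + [iv("chr2", 0, 100), iv("chr2", 9_900, 10_000)],
        )
        _, per_chrom_mean = loop_lengths(mars, aggregate="per_chromosome_mean")
        _, global_mean = loop_lengths(mars, aggregate="global_mean")
        assert per_chrom_mean != pytest.approx(global_mean)


class TestDensityCorrelation:
    def test_perfect_linearity(self):
        df = pd.DataFrame({"x": np.arange(28.0), "y": 2 * np.arange(28.0)})
        out = density_correlation(df, "x", "y")
        assert out["r"] == pytest.approx(1.0)
        assert out["n"] == 28

    def test_matches_closed_form_on_permuted_data(self, rng):
        x = rng.normal(size=28)
        y = rng.permutation(rng.normal(size=28))
        df = pd.DataFrame({"x": x, "y": y})
        out = density_correlation(df, "x", "y")
        assert out["r"] == pytest.approx(pearson_oracle(x, y))
        assert abs(out["r"]) < 0.5

    def test_zero_variance_reported_missing(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        out = density_correlation(df, "x", "y")
        assert np.isnan(out["r"])

    def test_requires_three_chromosomes(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            density_correlation(df, "x", "y")


@pytest.fixture(scope="module")
def gene():
    # gene on chr1 spanning [1000, 5000) with two exons and one intron
    return GeneModel(
        "g1", "chr1", "+", 1000, 5000, exons=((1000, 1500), (4000, 5000))
    )


class TestClassifyContext:
    def test_precedence_exon_over_intron(self, gene):
        mars = IntervalSet(
            "t",
            [
                iv("chr1", 1100, 1200),  # inside exon
                iv("chr1", 1400, 1600),  # straddles exon and intron -> exonic
                iv("chr1", 2000, 2100),  # intron only
                iv("chr1", 8000, 8100),  # outside gene
            ],
        )
        counts, labels = classify_context(mars, [gene])
        assert labels == ["exonic", "exonic", "intronic", "non-genic"]
        assert (counts.n_exonic, counts.n_intronic, counts.n_nongenic) == (2, 1, 1)
        assert counts.total == len(mars)

    def test_planted_contexts_recovered(self):
        cfg = SyntheticConfig(seed=5)
        genes = make_gene_models(cfg)
        sizes = {c: cfg.chrom_size_bp for c in cfg.chrom_names}
        peaks, truth_labels = plant_context_peaks(genes, sizes, 100, 100, 100, seed=5)
        counts, labels = classify_context(peaks, genes)
        assert labels == truth_labels
        assert (counts.n_exonic, counts.n_intronic, counts.n_nongenic) == (100, 100, 100)


class TestTSSProfile:
    def test_midpoint_at_plus_strand_tss_is_zero(self, gene):
        mars = IntervalSet("t", [iv("chr1", 950, 1050)])  # midpoint 1000 == TSS
        profile = tss_profile(mars, [gene], window=10_000, bin=1_000)
        assert profile.counts.sum() == 1
        assert profile.counts[10] == 1  # bin [0, 1000)

    def test_minus_strand_sign_convention(self):
        g = GeneModel("g1", "chr1", "-", 10_000, 20_000, exons=((10_000, 20_000),))
        # TSS at 19999; a MAR 5 kb 5' of the gene (at 24999) is upstream: -5000
        mars = IntervalSet("t", [iv("chr1", 24_949, 25_049)])
        profile = tss_profile(mars, [g], window=10_000, bin=1_000)
        d_bin = profile.to_frame()
        hit = d_bin[d_bin["count"] > 0]
        assert hit["bin_start"].item() == -5000

    def test_planted_normal_distances_peak_at_zero(self):
        cfg = SyntheticConfig(seed=8)
        genes = make_gene_models(cfg)
        sizes = {c: cfg.chrom_size_bp for c in cfg.chrom_names}
        peaks = plant_tss_peaks(genes, sizes, 300, sigma_bp=5000, seed=8)
        profile = tss_profile(peaks, genes, window=100_000, bin=10_000)
        assert profile.modal_bin_start in (-10_000, 0)
        # the two central bins hold the bulk of the mass
        centre = profile.counts[9] + profile.counts[10]
        assert centre / profile.counts.sum() > 0.8

    def test_translation_invariance(self, gene):
        mars = IntervalSet("t", [iv("chr1", 3000, 3200), iv("chr1", 7000, 7100)])
        p1 = tss_profile(mars, [gene], window=10_000, bin=1_000)
        shift = 12_345
        mars2 = IntervalSet(
            "t", [iv("chr1", i.start + shift, i.end + shift) for i in mars]
        )
        gene2 = GeneModel(
            "g1", "chr1", "+", gene.start + shift, gene.end + shift,
            exons=tuple((s + shift, e + shift) for s, e in gene.exons),
        )
        p2 = tss_profile(mars2, [gene2], window=10_000, bin=1_000)
        assert (p1.counts == p2.counts).all()

    def test_no_genes_errors(self):
        with pytest.raises(ValueError):
            tss_profile(IntervalSet("t", []), [], window=1000, bin=100)


class TestGeneFlankReport:
    def test_window_arithmetic(self):
        g = GeneModel("FIBH", "chr25", "+", 1_000_000, 1_020_000)
        report = gene_flank_report({"SG1": IntervalSet("SG1", [])}, g, 800_000)
        assert report["window"] == (200_000, 1_820_000)

    def test_flank_zero_keeps_only_gene_body_overlaps(self, gene):
        sets = {
            "SG1": IntervalSet(
                "SG1", [iv("chr1", 900, 1001), iv("chr1", 500, 900), iv("chr1", 6000, 6100)]
            )
        }
        report = gene_flank_report(sets, gene, 0)
        assert report["counts"]["SG1"] == 1

    def test_planted_flank_design_recovered(self):
        design = {
            "onlyA": 1, "onlyB": 8, "onlyC": 24,
            "AB_only": 0, "AC_only": 0, "BC_only": 0, "ABC": 3,
        }
        cfg = SyntheticConfig(seed=13, venn_design=design, n_chroms=1)
        sets, _ = make_peak_sets(cfg)
        # the 800 kb flanks of a central gene cover the whole 1.6 Mb chromosome
        g = GeneModel("FIBH", "chr1", "+", 800_000, 820_000)
        report = gene_flank_report(sets, g, 800_000)
        assert report["venn"].counts == design
        assert report["counts"] == {"SG1": 4, "SG5": 11, "SG7": 27}


class TestPathwayJoin:
    def test_simple_counts_and_unmapped(self):
        mapping = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "pathway": ["P1", "P1"]}
        )
        counts, unmapped = pathway_join(["g1", "g2", "g3"], mapping)
        assert counts["P1"] == 2
        assert unmapped == ["g3"]

    def test_empty_mapping_errors(self):
        with pytest.raises(ValueError):
            pathway_join(["g1"], pd.DataFrame(columns=["gene_id", "pathway"]))

    def test_matches_hash_join_oracle(self, rng):
        genes = [f"g{i}" for i in range(50)]
        pathways = [f"P{i}" for i in range(8)]
        rows = [
            {"gene_id": g, "pathway": pathways[int(rng.integers(8))]}
            for g in genes
            for _ in range(int(rng.integers(1, 3)))
        ]
        mapping = pd.DataFrame(rows).drop_duplicates()
        query = [g for g in genes if rng.random() < 0.6] + ["missing1"]
        counts, unmapped = pathway_join(query, mapping)
        # brute-force dict join
        expected: dict[str, set] = {}
        mapped = set()
        for row in mapping.itertuples():
            if row.gene_id in query:
                expected.setdefault(row.pathway, set()).add(row.gene_id)
                mapped.add(row.gene_id)
        assert {k: len(v) for k, v in expected.items()} == counts.to_dict()
        assert unmapped == sorted(set(query) - mapped)
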