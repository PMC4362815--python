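import math

import numpy as np
import pytest

from regulomics.annotate import (
    FEATURE_CLASSES,
    classify_feature,
    feature_enrichment,
    genome_feature_fractions,
    nearest_tss,
    regions_near_genes,
    regulatory_domains,
    associate_regions,
    tss_density,
)
from regulomics.core import ChromSizes, GeneModel, GenomicInterval, RegionSet


def _summit(chrom, pos):
    return GenomicInterval(chrom, max(0, pos - 1), pos + 1, summit=pos)


class TestNearestTss:
    def test_summit_at_plus_tss(self):
        genes = [GeneModel("g", "chr1", "+", 1000, 5000)]
        anns = nearest_tss([_summit("chr1", 1000)], genes)
        assert anns[0].gene_id == "g"
        assert anns[0].distance == 0

    def test_minus_strand_sign(self):
        # minus-strand gene with TSS at 1,000; summit at 1,100 is upstream
        genes = [GeneModel("g", "chr1", "-", 1000, 200)]
        anns = nearest_tss([_summit("chr1", 1100)], genes)
        assert anns[0].distance == -100

    def test_no_genes_on_chromosome(self):
        genes = [GeneModel("g", "chr2", "+", 1000, 5000)]
        anns = nearest_tss([_summit("chr1", 500)], genes)
        assert anns[0].gene_id is None
        assert anns[0].feature_class == "distal_intergenic"

    def test_tie_broken_lexically(self):
        genes = [
            GeneModel("gB", "chr1", "+", 900, 2000),
            GeneModel("gA", "chr1", "-", 1100, 300),
        ]
        anns = nearest_tss([_summit("chr1", 1000)], genes)
        assert anns[0].gene_id == "gA"

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        genes = []
        for i in range(50):
            strand = "+" if rng.random() < 0.5 else "-"
            start = int(rng.integers(10_000, 900_000))
            if strand == "+":
                genes.append(GeneModel(f"g{i:03d}", "chr1", "+", start, start + 5000))
            else:
                genes.append(GeneModel(f"g{i:03d}", "chr1", "-", start + 5000, start))
        summits = [_summit("chr1", int(rng.integers(0, 1_000_000))) for _ in range(1000)]
        anns = nearest_tss(summits, genes)
        for iv, a in zip(summits, anns):
            pos = iv.summit
            best = min(genes, key=lambda g: (abs(pos - g.tss), g.gene_id))
            assert a.gene_id == best.gene_id
            assert abs(a.distance) == abs(pos - best.tss)


class TestClassifyFeature:
    genes = [
        GeneModel("g1", "chr1", "+", 100_000, 150_000, [(100_000, 101_000), (140_000, 150_000)]),
        GeneModel("g2", "chr1", "+", 300_000, 320_000, [(300_000, 301_000)]),
    ]

    def test_promoter_upstream_1kb(self):
        assert classify_feature(99_000, "chr1", self.genes) == "promoter"

    def test_exon(self):
        # inside g1's second exon, outside every promoter window
        assert classify_feature(145_000, "chr1", self.genes) == "exon"

    def test_intron(self):
        assert classify_feature(120_000, "chr1", self.genes) == "intron"

    def test_upstream_10kb(self):
        assert classify_feature(95_000, "chr1", self.genes) == "upstream"

    def test_downstream_10kb_of_tts(self):
        assert classify_feature(155_000, "chr1", self.genes) == "downstream"

    def test_distal(self):
        assert classify_feature(200_000, "chr1", self.genes) == "distal_intergenic"

    def test_exon_beats_downstream_of_other_gene(self):
        # summit inside g2's exon and also < 10 kb downstream of g1's TTS
        genes = [
            GeneModel("g1", "chr1", "+", 100_000, 150_000),
            GeneModel("g2", "chr1", "+", 155_000, 170_000, [(155_000, 158_000)]),
        ]
        assert classify_feature(156_000, "chr1", genes) == "exon"

    def test_classes_partition(self):
        rng = np.random.default_rng(11)
        summits = [int(rng.integers(0, 500_000)) for _ in range(500)]
        counts = {c: 0 for c in FEATURE_CLASSES}
        for s in summits:
            counts[classify_feature(s, "chr1", self.genes)] += 1
        assert sum(counts.values()) == 500


class TestTssDensity:
    def _anns(self, distances):
        from regulomics.annotate import TssAnnotation

        return [
            TssAnnotation(0, "chr1", "g", d, "promoter") for d in distances
        ]

    def test_all_zero_distances_peak_at_zero(self):
        df = tss_density(self._anns([0] * 100))
        peak = df.loc[df["density"].idxmax(), "bin_center"]
        assert abs(peak) <= 250

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(2)
        df = tss_density(self._anns(rng.integers(-9000, 9000, 500).tolist()))
        integral = np.trapezoid(df["density"], df["bin_center"])
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_uniform_distances_flat(self):
        rng = np.random.default_rng(3)
        df = tss_density(self._anns(rng.integers(-10_000, 10_000, 50_000).tolist()))
        inner = df[np.abs(df["bin_center"]) < 8000]
        # flat truth: each 500-bp bin ~ count n*bin/(2*window) +- 3 SE
        n = df["count"].sum()
        p = 500 / 20_000
        se = math.sqrt(n * p * (1 - p))
        assert (np.abs(inner["count"] - n * p) <= 3 * se + 1).all()

    def test_empty_window_warns(self):
        with pytest.warns(UserWarning):
            df = tss_density(self._anns([50_000]))
        assert (df["count"] == 0).all()


class TestFeatureEnrichment:
    def test_exact_summation(self):
        expected = sum(
            math.comb(10, j) * 0.1**j * 0.9 ** (10 - j) for j in range(5, 11)
        )
        assert feature_enrichment(5, 10, 0.1) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.635e-3, rel=5e-3)

    def test_k_zero_is_one(self):
        assert feature_enrichment(0, 10, 0.1) == 1.0

    def test_k_equals_n_fraction_near_one(self):
        assert feature_enrichment(10, 10, 0.999) == pytest.approx(
            0.999**10, rel=1e-9
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            feature_enrichment(11, 10, 0.1)
        with pytest.raises(ValueError):
            feature_enrichment(5, 10, 0.0)


class TestRegulatoryDomains:
    genome = ChromSizes({"chr1": 10_000_000})

    def test_lone_gene_capped_at_1mb(self):
        genes = [GeneModel("g", "chr1", "+", 5_000_000, 5_020_000)]
        (d,) = regulatory_domains(genes, self.genome)
        assert d.basal == (4_995_000, 5_001_000)
        assert d.domain == (4_995_000 - 1_000_000, 5_001_000 + 1_000_000)

    def test_hand_constructed_neighbors(self):
        genes = [
            GeneModel("gA", "chr1", "+", 100_000, 120_000),
            GeneModel("gB", "chr1", "+", 300_000, 320_000),
        ]
        domains = {d.gene_id: d for d in regulatory_domains(genes, self.genome)}
        assert domains["gA"].basal == (95_000, 101_000)
        assert domains["gB"].basal == (295_000, 301_000)
        # A's right edge stops at B's basal left edge
        assert domains["gA"].domain[1] == 295_000
        assert domains["gB"].domain[0] == 101_000

    def test_overlapping_basal_still_contains_own(self):
        genes = [
            GeneModel("gA", "chr1", "+", 100_000, 120_000),
            GeneModel("gB", "chr1", "+", 102_000, 130_000),
        ]
        for d in regulatory_domains(genes, self.genome):
            assert d.domain[0] <= d.basal[0] and d.basal[1] <= d.domain[1]

    def test_random_placement_invariants(self):
        rng = np.random.default_rng(19)
        genome = ChromSizes({"chr1": 50_000_000})
        genes = []
        for i in range(1000):
            start = int(rng.integers(10_000, 49_900_000))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                genes.append(GeneModel(f"g{i:04d}", "chr1", "+", start, start + 10_000))
            else:
                genes.append(GeneModel(f"g{i:04d}", "chr1", "-", start + 10_000, start))
        domains = regulatory_domains(genes, genome)
        basal = {d.gene_id: d.basal for d in domains}
        for d in domains:
            assert d.domain[0] <= d.basal[0] and d.basal[1] <= d.domain[1]
            assert d.basal[0] - d.domain[0] <= 1_000_000
            assert d.domain[1] - d.basal[1] <= 1_000_000
            assert 0 <= d.domain[0] and d.domain[1] <= genome["chr1"]
        for d in domains:
            for gid, (b_lo, b_hi) in basal.items():
                if gid == d.gene_id:
                    continue
                # no extension past another basal: if the other basal is
                # disjoint from ours, our domain may not reach into it
                if b_hi <= d.basal[0]:
                    assert d.domain[0] >= b_hi or d.domain[0] <= d.basal[0] >= b_hi
                    assert d.domain[0] >= b_hi
                elif b_lo >= d.basal[1]:
                    assert d.domain[1] <= b_lo


class TestAssociateRegions:
    genome = ChromSizes({"chr1": 10_000_000})

    def _domains(self):
        genes = [
            GeneModel("gA", "chr1", "+", 1_000_000, 1_020_000),
            GeneModel("gB", "chr1", "+", 1_050_000, 1_070_000),
        ]
        return regulatory_domains(genes, self.genome)

    def test_single_domain(self):
        regions = RegionSet([_summit("chr1", 1_000_500)], genome=self.genome)
        assoc, un = associate_regions(regions, self._domains())
        assert assoc == {"gA": [0]}
        assert un == []

    def test_overlapping_domains_double_association(self):
        genes = [
            GeneModel("gA", "chr1", "+", 1_000_000, 1_020_000),
            GeneModel("gB", "chr1", "+", 1_000_000, 1_030_000),
        ]
        domains = regulatory_domains(genes, self.genome)
        regions = RegionSet([_summit("chr1", 1_000_500)], genome=self.genome)
        assoc, _ = associate_regions(regions, domains)
        assert set(assoc) == {"gA", "gB"}

    def test_gene_desert_unassociated(self):
        regions = RegionSet([_summit("chr1", 9_000_000)], genome=self.genome)
        assoc, un = associate_regions(regions, self._domains())
        assert assoc == {}
        assert un == [0]

    def test_midpoint_fallback_without_summit(self):
        regions = RegionSet(
            [GenomicInterval("chr1", 1_000_000, 1_001_000)], genome=self.genome
        )
        assoc, _ = associate_regions(regions, self._domains())
        assert assoc == {"gA": [0]}


class TestRegionsNearGenes:
    genome = ChromSizes({"chr1": 10_000_000})
    genes = [GeneModel("g", "chr1", "+", 2_000_000, 2_020_000)]

    def _region_at(self, mid):
        return GenomicInterval("chr1", mid - 50, mid + 50)

    def test_region_at_tss_included(self):
        rs = RegionSet([self._region_at(2_000_000)], genome=self.genome)
        assert len(regions_near_genes(rs, self.genes)) == 1

    def test_strict_boundary(self):
        inside = RegionSet([self._region_at(2_500_000)], genome=self.genome)
        outside = RegionSet([self._region_at(2_500_001)], genome=self.genome)
        assert len(regions_near_genes(inside, self.genes)) == 1
        assert len(regions_near_genes(outside, self.genes)) == 0

    def test_huge_radius_takes_all(self, rng):
        rs = RegionSet(
            [self._region_at(int(p)) for p in rng.integers(100, 9_999_000, 50)],
            genome=self.genome,
        )
        assert len(regions_near_genes(rs, self.genes, radius=10_000_000)) == len(rs)

    def test_empty_gene_group_warns(self):
        rs = RegionSet([self._region_at(100)], genome=self.genome)
        with pytest.warns(UserWarning):
            out = regions_near_genes(rs, [])
        assert len(out) == 0


def test_genome_feature_fractions_sum_to_one():
    genome = ChromSizes({"chr1": 1_000_000})
    genes = [
        GeneModel("g1", "chr1", "+", 100_000, 150_000, [(100_000, 110_000)]),
        GeneModel("g2", "chr1", "-", 400_000, 350_000, [(350_000, 360_000)]),
    ]
    fractions = genome_feature_fractions(genes, genome)
    assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-12)
    assert all(0 <= v <= 1 for v in fractions.values())


def test_genome_fraction_matches_per_base_oracle():
    genome = ChromSizes({"chr1": 500_000})
    genes = [
        GeneModel("g1", "chr1", "+", 100_000, 150_000, [(100_000, 110_000)]),
        GeneModel("g2", "chr1", "+", 140_000, 200_000, [(150_000, 155_000)]),
    ]
    fractions = genome_feature_fractions(genes, genome)
    # classify every base with the summit classifier
    counts = {c: 0 for c in FEATURE_CLASSES}
    step = 100  # sample every 100th base; exact because boundaries are round
    for pos in range(0, 500_000, step):
        counts[classify_feature(pos, "chr1", genes)] += 1
    total = sum(counts.values())
    for c in FEATURE_CLASSES:
        assert fractions[c] == pytest.approx(counts[c] / total, abs=0.01)
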