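"""Gene assignment, feature localization, meta-gene and coverage statistics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from gammamap.annotate import (assign_genes, chrom_coverage_stats,
                               classify_region_location, extend_interval,
                               metagene_profile, union_coverage)
from gammamap.core import GeneModel, GenomicInterval, TagLibrary


def gene(gid, chrom, start, end, strand="+"):
    return GeneModel(gene_id=gid, name=gid,
                     interval=GenomicInterval(chrom, start, end, strand),
                     strand=strand)


class TestExtendInterval:
    @pytest.mark.parametrize("iv, flank, length, expected", [
        ((100, 200), 10_000, 1_000_000, (0, 10_200)),
        ((100, 200), 0, 1_000_000, (100, 200)),
        ((999_900, 999_950), 10_000, 1_000_000, (989_900, 1_000_000)),
    ])
    def test_clipping(self, iv, flank, length, expected):
        got = extend_interval(GenomicInterval("chr1", *iv), flank, length)
        assert (got.start, got.end) == expected

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            extend_interval(GenomicInterval("chr1", 0, 10), -1, 100)


class TestAssignGenes:
    GENES = [gene("g1", "chr1", 1_000, 5_000),
             gene("g2", "chr1", 6_000, 9_000),
             gene("g3", "chr1", 50_000, 60_000),
             gene("g4", "chr2", 0, 4_000)]

    def test_region_spanning_two_genes(self):
        res = assign_genes([GenomicInterval("chr1", 4_000, 7_000)],
                           self.GENES, flank=0)
        assert res.region_genes == [["g1", "g2"]]
        assert res.n_regions_multi == 1

    def test_intergenic_region_no_genes(self):
        res = assign_genes([GenomicInterval("chr1", 20_000, 25_000)],
                           self.GENES, flank=0)
        assert res.region_genes == [[]]
        assert res.n_regions_zero == 1

    def test_flank_reaches_nearby_gene(self):
        # gene 5 kb away from the region edge, 10 kb flank
        res = assign_genes([GenomicInterval("chr1", 40_000, 45_000)],
                           self.GENES, flank=10_000)
        assert res.region_genes == [["g3"]]

    def test_matches_bruteforce_all_pairs(self, rng):
        """Sweep assignment equals the quadratic all-pairs oracle."""
        for _ in range(5):
            genes = [gene(f"g{i}", f"chr{rng.integers(1, 3)}",
                          s := int(rng.integers(0, 500_000)),
                          s + int(rng.integers(100, 20_000)))
                     for i in range(200)]
            regions = [GenomicInterval(f"chr{rng.integers(1, 3)}",
                                       s := int(rng.integers(0, 500_000)),
                                       s + int(rng.integers(100, 30_000)))
                       for _ in range(200)]
            flank = int(rng.choice([0, 5_000, 10_000]))
            got = assign_genes(regions, genes, flank=flank,
                               chrom_sizes={"chr1": 10**6, "chr2": 10**6})
            for region, hits in zip(regions, got.region_genes):
                oracle = [g.gene_id for g in genes
                          if g.interval.chrom == region.chrom
                          and g.interval.start < region.end + flank
                          and region.start - flank < g.interval.end]
                assert sorted(hits) == sorted(oracle)


class TestClassifyRegionLocation:
    GENE_PLUS = gene("g", "chr1", 10_000, 20_000, "+")
    GENE_MINUS = gene("g", "chr1", 10_000, 20_000, "-")

    @pytest.mark.parametrize("span, g, expected", [
        ((12_000, 15_000), GENE_PLUS, "gene-body"),
        ((9_000, 11_000), GENE_PLUS, "TSS-overlapping"),
        ((19_000, 21_000), GENE_PLUS, "TES-overlapping"),
        ((9_000, 11_000), GENE_MINUS, "TES-overlapping"),
        ((19_000, 21_000), GENE_MINUS, "TSS-overlapping"),
        ((2_000, 8_000), GENE_PLUS, "upstream"),
        ((22_000, 28_000), GENE_PLUS, "downstream"),
        ((2_000, 8_000), GENE_MINUS, "downstream"),
    ])
    def test_classes(self, span, g, expected):
        region = GenomicInterval("chr1", *span)
        assert classify_region_location(region, g, flank=10_000) == expected

    def test_tss_precedence_over_everything(self):
        region = GenomicInterval("chr1", 5_000, 25_000)  # covers whole gene
        assert classify_region_location(region, self.GENE_PLUS) \
            == "TSS-overlapping"


class TestMetagene:
    CHROMS = {"chr1": 400_000}

    def _uniform_lib(self, rng, n, label):
        return TagLibrary({"chr1": rng.integers(0, 400_000, size=n)},
                          label=label)

    def test_uniform_chip_equals_control_is_flat_zero(self):
        rng = np.random.default_rng(5)
        genes = [gene(f"g{i}", "chr1", 30_000 + 40_000 * i,
                      30_000 + 40_000 * i + 20_000) for i in range(8)]
        n = 200_000
        chip = self._uniform_lib(rng, n, "chip")
        ctrl = self._uniform_lib(rng, n, "ctrl")
        prof = metagene_profile(chip, ctrl, genes, n_body_bins=20,
                                flank_bp=10_000, flank_bin_bp=1_000,
                                chrom_sizes=self.CHROMS)
        # sampling-noise bound: bin density RPM/kb, per-bin Poisson counts
        all_bins = np.concatenate([prof.upstream, prof.body, prof.downstream])
        lam_flank = n * 1_000 / 400_000          # counts per 1 kb bin
        se = np.sqrt(2 * lam_flank) * 1e6 / n / 1.0 / np.sqrt(len(genes))
        assert np.abs(all_bins).max() < 4 * se

    def test_body_restricted_signal(self):
        genes = [gene("g1", "chr1", 100_000, 120_000)]
        chip = TagLibrary({"chr1": np.linspace(100_000, 119_999, 5_000,
                                               dtype=int)})
        ctrl = TagLibrary({"chr1": np.linspace(0, 399_999, 5_000, dtype=int)})
        prof = metagene_profile(chip, ctrl, genes, n_body_bins=10,
                                flank_bp=10_000, flank_bin_bp=1_000,
                                chrom_sizes=self.CHROMS)
        assert prof.body.min() > max(prof.upstream.max(),
                                     prof.downstream.max())

    def test_strand_flip_mirrors_profile(self):
        rng = np.random.default_rng(6)
        plus = [gene("g1", "chr1", 100_000, 130_000, "+")]
        minus = [gene("g1", "chr1", 100_000, 130_000, "-")]
        chip = TagLibrary({"chr1": rng.integers(90_000, 140_000, size=50_000)})
        ctrl = self._uniform_lib(rng, 50_000, "ctrl")
        p = metagene_profile(chip, ctrl, plus, n_body_bins=10,
                             flank_bp=10_000, flank_bin_bp=1_000,
                             chrom_sizes=self.CHROMS)
        m = metagene_profile(chip, ctrl, minus, n_body_bins=10,
                             flank_bp=10_000, flank_bin_bp=1_000,
                             chrom_sizes=self.CHROMS)
        full_p = np.concatenate([p.upstream, p.body, p.downstream])
        full_m = np.concatenate([m.upstream, m.body, m.downstream])
        np.testing.assert_allclose(full_m, full_p[::-1])

    def test_short_gene_skipped(self):
        genes = [gene("tiny", "chr1", 100_000, 100_005),
                 gene("ok", "chr1", 200_000, 220_000)]
        rng = np.random.default_rng(7)
        prof = metagene_profile(self._uniform_lib(rng, 10_000, "c"),
                                self._uniform_lib(rng, 10_000, "k"),
                                genes, n_body_bins=10, flank_bp=5_000,
                                flank_bin_bp=1_000, chrom_sizes=self.CHROMS)
        assert prof.n_genes == 1


class TestChromCoverage:
    def test_doubled_coverage_gives_slope_two(self):
        genes, regions = [], []
        for i, chrom in enumerate(["chr1", "chr2", "chr3"], start=1):
            genes.append(gene(f"g{chrom}", chrom, 0, 1_000 * i))
            regions.append(GenomicInterval(chrom, 10_000, 10_000 + 2_000 * i))
        table, r, slope, intercept = chrom_coverage_stats(regions, genes)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)

    def test_perfect_negative_collinearity(self):
        # exon coverage 1,2,3 kb against region coverage 5,3,1 kb
        genes, regions = [], []
        for chrom, ex_kb, reg_kb in [("chr1", 1, 5), ("chr2", 2, 3),
                                     ("chr3", 3, 1)]:
            genes.append(gene(f"g{chrom}", chrom, 0, 1_000 * ex_kb))
            regions.append(GenomicInterval(chrom, 50_000,
                                           50_000 + 1_000 * reg_kb))
        _, r, _, _ = chrom_coverage_stats(regions, genes)
        assert r == pytest.approx(-1.0)

    def test_single_chromosome_raises(self):
        with pytest.raises(ValueError):
            chrom_coverage_stats([GenomicInterval("chr1", 0, 10)],
                                 [gene("g1", "chr1", 0, 100)])

    def test_independent_coverages_rarely_correlate(self, rng):
        """Null check: random coverage pairs over 20 chromosomes."""
        strong = 0
        n_trials = 100
        for _ in range(n_trials):
            genes, regions = [], []
            for i in range(20):
                chrom = f"chr{i}"
                genes.append(gene(f"g{i}", chrom, 0,
                                  int(rng.integers(1_000, 100_000))))
                regions.append(GenomicInterval(
                    chrom, 200_000, 200_000 + int(rng.integers(1_000,
                                                               100_000))))
            _, r, _, _ = chrom_coverage_stats(regions, genes)
            strong += abs(r) >= 0.6
        assert strong <= 5


@given(hst.lists(hst.tuples(hst.integers(0, 10_000), hst.integers(1, 2_000)),
                 min_size=1, max_size=20))
@settings(max_examples=50, deadline=None)
def test_union_coverage_split_invariant(raw):
    """Coverage is invariant to order and to splitting regions in half."""
    ivs = [GenomicInterval("chr1", s, s + ln) for s, ln in raw]
    base = union_coverage(ivs)
    shuffled = union_coverage(list(reversed(ivs)))
    halves = []
    for iv in ivs:
        mid = (iv.start + iv.end) // 2
        if mid > iv.start and mid < iv.end:
            halves += [GenomicInterval("chr1", iv.start, mid),
                       GenomicInterval("chr1", mid, iv.end)]
        else:
            halves.append(iv)
    assert base == shuffled == union_coverage(halves)
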