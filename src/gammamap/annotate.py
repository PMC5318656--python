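"""Relating called damage regions to gene models.

Overlap assignment with flank extension, gene-feature localization of each
region, meta-gene profiles contrasting gene bodies against flanks, and
per-chromosome region-vs-exon coverage statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import GeneModel, GenomicInterval, TagLibrary

__all__ = [
    "RegionGeneAssignment",
    "MetaGeneProfile",
    "extend_interval",
    "assign_genes",
    "classify_region_location",
    "metagene_profile",
    "chrom_coverage_stats",
]

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("TSS-overlapping", "gene-body", "TES-overlapping",
                   "upstream", "downstream")


def extend_interval(iv: GenomicInterval, flank: int,
                    chrom_length: int) -> GenomicInterval:
    """Extend both ends by ``flank`` bp, clipped to [0, chrom_length)."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    return GenomicInterval(iv.chrom, max(0, iv.start - flank),
                           min(chrom_length, iv.end + flank), iv.strand)


@dataclass
class RegionGeneAssignment:
    """Region-to-gene overlap map plus the headline summary counts."""

    region_genes: List[List[str]]        # parallel to the input regions
    n_regions_zero: int
    n_regions_one: int
    n_regions_multi: int
    n_distinct_genes: int

    @property
    def gene_ids(self) -> List[str]:
        return sorted({g for lst in self.region_genes for g in lst})


def assign_genes(regions: Sequence, genes: Sequence[GeneModel],
                 flank: int = 0,
                 chrom_sizes: Optional[Mapping[str, int]] = None,
                 ) -> RegionGeneAssignment:
    """Assign genes to flank-extended regions by strand-blind intersection.

    A gene is assigned iff its interval shares >= 1 bp with the extended
    region. Summary counts report regions hitting 0, exactly 1, or more
    than 1 gene, and the number of distinct genes hit overall.
    """
    trees: Dict[str, IntervalTree] = {}
    for i, g in enumerate(genes):
        trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, i)

    region_genes: List[List[str]] = []
    for r in regions:
        iv = r.interval if hasattr(r, "interval") else r
        size = (chrom_sizes or {}).get(iv.chrom)
        ext = extend_interval(iv, flank, size if size is not None
                              else iv.end + flank)
        tree = trees.get(ext.chrom)
        hits = sorted(tree.overlap(ext.start, ext.end),
                      key=lambda h: h.data) if tree else []
        region_genes.append([genes[h.data].gene_id for h in hits])

    counts = [len(lst) for lst in region_genes]
    return RegionGeneAssignment(
        region_genes=region_genes,
        n_regions_zero=sum(1 for c in counts if c == 0),
        n_regions_one=sum(1 for c in counts if c == 1),
        n_regions_multi=sum(1 for c in counts if c > 1),
        n_distinct_genes=len({g for lst in region_genes for g in lst}),
    )


def classify_region_location(region: GenomicInterval, gene: GeneModel,
                             flank: int = 10_000) -> str:
    """Locate a region relative to one assigned gene.

    Precedence: TSS-overlapping > TES-overlapping > gene-body; regions not
    touching the gene are upstream/downstream of it (strand-aware) within
    ``flank``.
    """
    if region.chrom != gene.interval.chrom:
        raise ValueError("region and gene on different chromosomes")
    if region.start <= gene.tss < region.end:
        return "TSS-overlapping"
    if region.start <= gene.tes < region.end:
        return "TES-overlapping"
    if region.overlaps(gene.interval):
        return "gene-body"
    if region.end <= gene.interval.start:
        left = True
    elif region.start >= gene.interval.end:
        left = False
    else:  # unreachable given the overlap test
        return "gene-body"
    gap = (gene.interval.start - region.end if left
           else region.start - gene.interval.end)
    if gap > flank:
        raise ValueError("region beyond flank of the assigned gene")
    if gene.strand == "+":
        return "upstream" if left else "downstream"
    return "downstream" if left else "upstream"


@dataclass
class MetaGeneProfile:
    """Length-normalized mean signal over a gene population.

    Bin values are control-adjusted chip densities (RPM per kb so body and
    flank bins share units) averaged over genes; minus-strand genes are
    flipped before accumulation so bin 0 of the body is always the TSS end.
    """

    upstream: np.ndarray
    body: np.ndarray
    downstream: np.ndarray
    n_genes: int
    flank_bp: int
    flank_bin_bp: int
    n_body_bins: int
    mode: str

    def as_frame(self) -> pd.DataFrame:
        bins = ([f"up{i}" for i in range(len(self.upstream))]
                + [f"body{i}" for i in range(len(self.body))]
                + [f"down{i}" for i in range(len(self.downstream))])
        return pd.DataFrame({
            "bin": bins,
            "mean": np.concatenate([self.upstream, self.body,
                                    self.downstream]),
            "n": self.n_genes,
        })


def _binned_density(lib: TagLibrary, chrom: str, edges: np.ndarray) -> np.ndarray:
    """RPM per kb within consecutive [edges[i], edges[i+1]) bins."""
    pos = lib.positions.get(chrom)
    if pos is None or len(pos) == 0:
        counts = np.zeros(len(edges) - 1)
    else:
        counts = np.diff(np.searchsorted(pos, edges, side="left")).astype(float)
    widths_kb = np.diff(edges) / 1000.0
    widths_kb[widths_kb == 0] = np.nan
    return counts * 1e6 / lib.total / widths_kb


def metagene_profile(chip: TagLibrary, ctrl: TagLibrary,
                     genes: Sequence[GeneModel],
                     n_body_bins: int = 100,
                     flank_bp: int = 10_000,
                     flank_bin_bp: int = 500,
                     mode: str = "subtract",
                     chrom_sizes: Optional[Mapping[str, int]] = None,
                     ) -> MetaGeneProfile:
    """Mean damage signal across scaled gene bodies and fixed-width flanks.

    Each gene body contributes ``n_body_bins`` equal fractions regardless
    of length; flanks are binned at ``flank_bin_bp``. Per bin the chip
    density is combined with the control density by subtraction or ratio
    (``mode``). Genes shorter than ``n_body_bins`` bp are skipped with a
    log entry.
    """
    if not genes:
        raise ValueError("gene list is empty")
    if mode not in ("subtract", "ratio"):
        raise ValueError(f"mode must be subtract|ratio: {mode!r}")
    n_flank_bins = flank_bp // flank_bin_bp
    acc = np.zeros(2 * n_flank_bins + n_body_bins)
    n_used = 0
    eps = 0.1  # RPM/kb pseudo-density for ratio mode

    for g in genes:
        if g.length < n_body_bins:
            logger.info("metagene: skipping %s (%d bp < %d bins)",
                        g.gene_id, g.length, n_body_bins)
            continue
        chrom = g.interval.chrom
        size = (chrom_sizes or {}).get(chrom)
        up_edges = g.interval.start - flank_bin_bp * np.arange(
            n_flank_bins, -1, -1)
        down_edges = g.interval.end + flank_bin_bp * np.arange(n_flank_bins + 1)
        body_edges = np.unique(np.round(np.linspace(
            g.interval.start, g.interval.end, n_body_bins + 1)).astype(np.int64))
        if len(body_edges) != n_body_bins + 1:
            logger.info("metagene: skipping %s (degenerate body bins)",
                        g.gene_id)
            continue
        lo, hi = 0, size if size is not None else down_edges[-1]
        if up_edges[0] < lo or down_edges[-1] > hi:
            logger.info("metagene: skipping %s (flank out of bounds)",
                        g.gene_id)
            continue
        vals = []
        for edges in (up_edges, body_edges, down_edges):
            c = _binned_density(chip, chrom, edges)
            k = _binned_density(ctrl, chrom, edges)
            vals.append(c - k if mode == "subtract"
                        else (c + eps) / (k + eps))
        profile = np.concatenate(vals)
        if g.strand == "-":
            profile = profile[::-1]
        acc += profile
        n_used += 1

    if n_used == 0:
        raise ValueError("no gene passed the meta-gene length/bounds filters")
    acc /= n_used
    return MetaGeneProfile(
        upstream=acc[:n_flank_bins],
        body=acc[n_flank_bins:n_flank_bins + n_body_bins],
        downstream=acc[n_flank_bins + n_body_bins:],
        n_genes=n_used, flank_bp=flank_bp, flank_bin_bp=flank_bin_bp,
        n_body_bins=n_body_bins, mode=mode)


def union_coverage(intervals: Sequence[GenomicInterval]) -> Dict[str, int]:
    """Union bp covered per chromosome (order-independent)."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: Dict[str, int] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        covered = 0
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
        covered += cur_e - cur_s
        out[chrom] = covered
    return out


def chrom_coverage_stats(regions: Sequence, genes: Sequence[GeneModel]
                         ) -> Tuple[pd.DataFrame, float, float, float]:
    """Per-chromosome region vs exon union coverage with Pearson r and fit.

    Returns (table, r, slope, intercept); raises when fewer than two
    chromosomes carry annotation, where a correlation is undefined.
    """
    region_ivs = [r.interval if hasattr(r, "interval") else r for r in regions]
    exon_ivs = [ex for g in genes for ex in (g.exons or (g.interval,))]
    reg_cov = union_coverage(region_ivs)
    ex_cov = union_coverage(exon_ivs)
    chroms = sorted(set(reg_cov) | set(ex_cov))
    if len(chroms) < 2:
        raise ValueError("correlation needs >= 2 chromosomes")
    table = pd.DataFrame({
        "chrom": chroms,
        "region_bp": [reg_cov.get(c, 0) for c in chroms],
        "exon_bp": [ex_cov.get(c, 0) for c in chroms],
    })
    r, _ = stats.pearsonr(table.exon_bp, table.region_bp)
    fit = stats.linregress(table.exon_bp, table.region_bp)
    return table, float(r), float(fit.slope), float(fit.intercept)
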