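"""Synthetic genome, annotation, expression and ChIP tag-library generator.

Emulates the inputs of a damage-mapping ChIP study on a toy genome with
fully recorded ground truth: a gene annotation with controlled neighborhood
orientation classes, a log-normal expression table over two oncogene
conditions, damage-mark tag libraries with broad gene-body-restricted
enrichment that grows with expression, a promoter-restricted active-chromatin
library, a matched uniform isotype control, and genome sequence with planted
R-loop-competent G-rich cassettes.

Every stochastic choice flows from a single integer seed, so all outputs are
byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval, TagLibrary

__all__ = [
    "GenomeSpec",
    "SimGene",
    "SimTruth",
    "SimStudy",
    "generate_annotation",
    "simulate_expression",
    "simulate_tags",
    "generate_sequence",
    "simulate_study",
    "write_fixture",
    "DEFAULT_PAIR_FRACTION",
]

DEFAULT_CHROM_SIZES = {"chr1": 10_000_000, "chr2": 10_000_000}
DEFAULT_PAIR_FRACTION = {
    "overlapping": 0.10,
    "isolated": 0.30,
    "tandem": 0.20,
    "convergent": 0.20,
    "divergent": 0.20,
}

_RIZ_CASSETTE = "GGGTTGGGTTGGG"
_RLFS_LINKER = "A" * 20
_RLFS_TAIL_BLOCKS = 2          # 100-nt blocks, each with exactly 60 G
_RLFS_TAIL_G_PER_BLOCK = 60

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class SizingError(ValueError):
    """Requested annotation does not fit in the genome at the spacing asked."""


@dataclass(frozen=True)
class GenomeSpec:
    """Toy genome layout: chromosome sizes, background GC, master seed."""

    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_SIZES))
    gc_background: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.chrom_sizes.values()):
            raise ValueError("all chromosome lengths must be > 0")
        if not 0.0 <= self.gc_background <= 1.0:
            raise ValueError("gc_background must be in [0, 1]")

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_sizes.values()))


@dataclass(frozen=True)
class SimGene:
    """A simulated gene: coordinates plus all planted ground-truth labels."""

    gene_id: str
    name: str
    interval: GenomicInterval
    strand: str
    exons: Tuple[GenomicInterval, ...]
    orientation_class: str = "isolated"
    lineage_tag: str = "none"            # lymphoid | myeloid | none
    planted_hotspot: bool = False
    hotspot_conditions: frozenset = field(default_factory=frozenset)
    planted_rlfs: bool = False

    @property
    def tss(self) -> int:
        return (self.interval.start if self.strand == "+"
                else self.interval.end - 1)

    def to_gene_model(self) -> GeneModel:
        return GeneModel(gene_id=self.gene_id, name=self.name,
                         interval=self.interval, strand=self.strand,
                         exons=self.exons)


@dataclass
class SimTruth:
    """Complete ground-truth bookkeeping for one simulated study."""

    hotspot_intervals: Dict[str, List[Tuple[GenomicInterval, float]]] = \
        field(default_factory=dict)
    rlfs_intervals: List[GenomicInterval] = field(default_factory=list)
    params: Dict = field(default_factory=dict)


@dataclass
class SimStudy:
    """Bundle of every artifact one simulated study produces."""

    spec: GenomeSpec
    genes: List[SimGene]
    expression: pd.DataFrame
    libraries: Dict[str, TagLibrary]
    sequences: Dict[str, str]
    truth: SimTruth


# ---------------------------------------------------------------------------
# annotation

def _make_exons(rng: np.random.Generator, iv: GenomicInterval,
                strand: str) -> Tuple[GenomicInterval, ...]:
    max_exons = max(1, min(8, iv.length // 600))
    n = int(rng.integers(1, max_exons + 1))
    if n == 1:
        return (GenomicInterval(iv.chrom, iv.start, iv.end, strand),)
    # cut the body into 2n-1 alternating exon/intron blocks
    cuts = np.sort(rng.choice(np.arange(1, iv.length), size=2 * n - 2,
                              replace=False))
    bounds = np.concatenate(([0], cuts, [iv.length])) + iv.start
    exons = tuple(GenomicInterval(iv.chrom, int(bounds[i]), int(bounds[i + 1]),
                                  strand)
                  for i in range(0, 2 * n - 1, 2))
    return exons


def _category_counts(n_genes: int, pair_fraction: Mapping[str, float]
                     ) -> Dict[str, int]:
    fracs = dict(DEFAULT_PAIR_FRACTION)
    if pair_fraction:
        unknown = set(pair_fraction) - set(fracs)
        if unknown:
            raise ValueError(f"unknown orientation classes: {sorted(unknown)}")
        fracs = {k: float(pair_fraction.get(k, 0.0)) for k in fracs}
    total = sum(fracs.values())
    if total <= 0:
        raise ValueError("pair_fraction must have positive mass")
    fracs = {k: v / total for k, v in fracs.items()}
    counts = {}
    for cat in ("overlapping", "tandem", "convergent", "divergent"):
        c = int(round(fracs[cat] * n_genes))
        counts[cat] = c - (c % 2)        # paired classes need even counts
    counts["isolated"] = n_genes - sum(counts.values())
    if counts["isolated"] < 0:
        # give back pairs until the budget balances
        for cat in ("tandem", "convergent", "divergent", "overlapping"):
            while counts["isolated"] < 0 and counts[cat] >= 2:
                counts[cat] -= 2
                counts["isolated"] += 2
    if counts["isolated"] < 0:
        raise ValueError("pair_fraction rounding cannot reach n_genes")
    return counts


def generate_annotation(
    spec: GenomeSpec,
    n_genes: int = 300,
    length_range: Tuple[int, int] = (2_000, 100_000),
    pair_fraction: Optional[Mapping[str, float]] = None,
    max_dist: int = 10_000,
    n_hotspot: int = 30,
    n_hotspot_a_only: int = 3,
    n_hotspot_b_only: int = 3,
    n_lineage_extra: int = 20,
    n_rlfs_background: int = 10,
    seed: Optional[int] = None,
) -> List[SimGene]:
    """Place genes in orientation-controlled units across the genome.

    Genes come in single-gene (isolated) or two-gene units (overlapping,
    tandem, convergent, divergent); units are separated by more than
    ``max_dist`` so each class is realized exactly at construction. Gene
    lengths are log-uniform over ``length_range``. A subset of genes (one
    per unit at most, so planted islands never fuse across a pair) is
    flagged as damage hotspots; shared and condition-A-only hotspots carry
    the lymphoid lineage tag, condition-B-only hotspots the myeloid tag,
    mirroring lineage-specific fragility.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    counts = _category_counts(n_genes, pair_fraction or {})

    def draw_len() -> int:
        lo, hi = np.log(length_range[0]), np.log(length_range[1])
        return int(np.exp(rng.uniform(lo, hi)))

    # build units: (category, [(rel_start, length, strand), ...])
    units: List[Tuple[str, List[Tuple[int, int, str]]]] = []
    for _ in range(counts["isolated"]):
        units.append(("isolated", [(0, draw_len(),
                                    "+" if rng.random() < 0.5 else "-")]))
    for cat in ("tandem", "convergent", "divergent"):
        for _ in range(counts[cat] // 2):
            l1, l2 = draw_len(), draw_len()
            gap = int(rng.integers(200, max_dist - 200))
            if cat == "tandem":
                s = "+" if rng.random() < 0.5 else "-"
                strands = (s, s)
            elif cat == "convergent":
                strands = ("+", "-")
            else:
                strands = ("-", "+")
            units.append((cat, [(0, l1, strands[0]),
                                (l1 + gap, l2, strands[1])]))
    for _ in range(counts["overlapping"] // 2):
        l1 = max(draw_len(), 3000)
        l2 = draw_len()
        off = int(rng.integers(l1 // 4, max(l1 // 4 + 1, 3 * l1 // 4)))
        strands = ("+" if rng.random() < 0.5 else "-",
                   "+" if rng.random() < 0.5 else "-")
        units.append(("overlapping", [(0, l1, strands[0]),
                                      (off, l2, strands[1])]))

    order = rng.permutation(len(units))
    spacing_min = max_dist + 1
    chrom_names = list(spec.chrom_sizes)
    cursors = {c: 0 for c in chrom_names}

    genes: List[SimGene] = []
    gene_no = 0
    for ui in order:
        cat, layout = units[ui]
        unit_len = max(rs + ln for rs, ln, _ in layout)
        spacing = spacing_min + int(rng.integers(0, 5_000))
        placed = False
        for chrom in sorted(chrom_names, key=lambda c: cursors[c]):
            start = cursors[chrom] + (spacing if cursors[chrom] > 0 else 0)
            if start + unit_len <= spec.chrom_sizes[chrom]:
                for rel, ln, strand in layout:
                    gene_no += 1
                    iv = GenomicInterval(chrom, start + rel, start + rel + ln,
                                         strand)
                    genes.append(SimGene(
                        gene_id=f"g{gene_no:04d}", name=f"Gene{gene_no:04d}",
                        interval=iv, strand=strand,
                        exons=_make_exons(rng, iv, strand),
                        orientation_class=cat))
                cursors[chrom] = start + unit_len
                placed = True
                break
        if not placed:
            raise SizingError(
                f"genome too small: unit of {unit_len} bp does not fit "
                f"with {spacing_min} bp spacing")

    genes.sort(key=lambda g: g.interval.sort_key())

    # hotspot / lineage / RLFS planting: at most one hotspot per unit so a
    # planted island can never fuse across a close gene pair. Units are
    # recovered from proximity: intra-unit gaps are < max_dist, inter-unit
    # spacing is > max_dist by construction.
    unit_of: Dict[int, int] = {}
    uid = -1
    prev_chrom: Optional[str] = None
    prev_max_end = -1
    for i, g in enumerate(genes):
        if (g.interval.chrom != prev_chrom
                or g.interval.start - prev_max_end > max_dist):
            uid += 1
            prev_max_end = -1
        unit_of[i] = uid
        prev_chrom = g.interval.chrom
        prev_max_end = max(prev_max_end, g.interval.end)

    n_hot = min(n_hotspot, len(genes))
    candidates = list(range(len(genes)))
    rng.shuffle(candidates)
    hot_idx: List[int] = []
    used_units = set()
    for i in candidates:
        if len(hot_idx) >= n_hot:
            break
        if unit_of[i] in used_units:
            continue
        hot_idx.append(i)
        used_units.add(unit_of[i])
    a_only = set(hot_idx[:n_hotspot_a_only])
    b_only = set(hot_idx[n_hotspot_a_only:n_hotspot_a_only + n_hotspot_b_only])
    shared = set(hot_idx) - a_only - b_only

    rlfs_idx = set(hot_idx)
    non_hot = [i for i in range(len(genes)) if i not in rlfs_idx]
    rng.shuffle(non_hot)
    rlfs_idx |= set(non_hot[:n_rlfs_background])
    extra_lym = set(non_hot[n_rlfs_background:n_rlfs_background + n_lineage_extra])
    extra_mye = set(non_hot[n_rlfs_background + n_lineage_extra:
                            n_rlfs_background + 2 * n_lineage_extra])

    out: List[SimGene] = []
    for i, g in enumerate(genes):
        conds = frozenset()
        lineage = "none"
        if i in shared:
            conds, lineage = frozenset({"A", "B"}), "lymphoid"
        elif i in a_only:
            conds, lineage = frozenset({"A"}), "lymphoid"
        elif i in b_only:
            conds, lineage = frozenset({"B"}), "myeloid"
        elif i in extra_lym:
            lineage = "lymphoid"
        elif i in extra_mye:
            lineage = "myeloid"
        out.append(replace(g, planted_hotspot=bool(conds),
                           hotspot_conditions=conds, lineage_tag=lineage,
                           planted_rlfs=i in rlfs_idx))
    return out


# ---------------------------------------------------------------------------
# expression

def simulate_expression(
    genes: Sequence[SimGene],
    mu: float = 1.0,
    sigma: float = 1.0,
    zero_fraction: float = 0.2,
    hotspot_boost: float = 2.0,
    de_fold: float = 8.0,
    n_de_random: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Log-normal FPKM per gene for the two oncogene conditions A and B.

    Exactly ``zero_fraction`` of genes are silent; planted hotspot genes
    draw from a boosted log-mean (damage tracks transcription). Condition-
    specific hotspot genes are differentially expressed toward their own
    condition by ``de_fold``; a further random gene set is differentially
    expressed in random directions without any damage consequence.
    """
    if not 0.0 <= zero_fraction <= 1.0:
        raise ValueError("zero_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(genes)
    n_zero = int(round(zero_fraction * n))
    zero_idx = set(rng.choice(n, size=n_zero, replace=False).tolist())

    base = np.exp(rng.normal(mu, sigma, size=n))
    fpkm_a = np.zeros(n)
    fpkm_b = np.zeros(n)
    for i, g in enumerate(genes):
        if i in zero_idx:
            continue
        v = base[i] * (np.exp(hotspot_boost) if g.planted_hotspot else 1.0)
        fa = fb = v
        if g.planted_hotspot and g.hotspot_conditions == {"A"}:
            fb = v / de_fold
        elif g.planted_hotspot and g.hotspot_conditions == {"B"}:
            fa = v / de_fold
        fpkm_a[i], fpkm_b[i] = fa, fb

    nonzero = [i for i in range(n) if i not in zero_idx
               and not genes[i].planted_hotspot]
    rng.shuffle(nonzero)
    for i in nonzero[:n_de_random]:
        if rng.random() < 0.5:
            fpkm_a[i] *= de_fold
        else:
            fpkm_b[i] *= de_fold

    return pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "fpkm_A": fpkm_a,
        "fpkm_B": fpkm_b,
    })


# ---------------------------------------------------------------------------
# tag libraries

def _uniform_positions(rng: np.random.Generator, n: int,
                       chrom_sizes: Mapping[str, int]) -> Dict[str, np.ndarray]:
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    alloc = rng.multinomial(n, sizes / sizes.sum())
    return {c: rng.integers(0, chrom_sizes[c], size=int(k))
            for c, k in zip(chroms, alloc)}


def simulate_tags(
    genes: Sequence[SimGene],
    expression: Optional[pd.DataFrame],
    n_reads: int,
    chrom_sizes: Mapping[str, int],
    enrichment: float = 5.0,
    expression_coef: float = 0.5,
    condition: str = "A",
    mode: str = "gene_body",
    promoter_halfwidth: int = 1_000,
    promoter_body_fraction: float = 0.0,
    control: bool = False,
    seed: int = 0,
    truth: Optional[SimTruth] = None,
) -> TagLibrary:
    """Draw a tag library: uniform background plus planted enrichment.

    A control library is purely uniform. Otherwise reads mix a uniform
    background with reads placed uniformly within enriched intervals: the
    gene bodies of hotspot genes active in ``condition`` (gene_body mode),
    or TSS +/- ``promoter_halfwidth`` of every expressed gene (promoter
    mode, emulating an active-chromatin mark). The per-base enrichment
    factor is 1 + (enrichment - 1) * (1 + expression_coef * log1p(FPKM)),
    a monotone signal-vs-expression law. In promoter mode a
    ``promoter_body_fraction`` > 0 additionally spreads that fraction of
    the enrichment over the whole gene body, emulating the broad
    acetylation of strongly active loci. Planted intervals and realized
    factors are recorded in ``truth`` when given.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = np.random.default_rng(seed)
    label = "control" if control else f"{mode}:{condition}"
    if n_reads == 0:
        return TagLibrary({c: [] for c in chrom_sizes}, label=label)

    genome = float(sum(chrom_sizes.values()))
    enriched: List[Tuple[GenomicInterval, float]] = []
    if not control and enrichment > 1.0:
        fcol = f"fpkm_{condition}"
        fpkm = ({} if expression is None else
                dict(zip(expression["gene_id"], expression[fcol])))
        for g in genes:
            f = float(fpkm.get(g.gene_id, 0.0))
            if mode == "gene_body":
                if not (g.planted_hotspot and condition in g.hotspot_conditions):
                    continue
                iv = g.interval
            elif mode == "promoter":
                if f <= 0.0:
                    continue
                size = chrom_sizes[g.interval.chrom]
                iv = GenomicInterval(
                    g.interval.chrom,
                    max(0, g.tss - promoter_halfwidth),
                    min(size, g.tss + promoter_halfwidth))
            else:
                raise ValueError(f"unknown mode: {mode!r}")
            factor = 1.0 + (enrichment - 1.0) * (
                1.0 + expression_coef * np.log1p(f))
            enriched.append((iv, factor))
            if mode == "promoter" and promoter_body_fraction > 0:
                body_factor = 1.0 + (factor - 1.0) * promoter_body_fraction
                enriched.append((g.interval, body_factor))

    weights = np.array([genome] + [iv.length * (f - 1.0)
                                   for iv, f in enriched])
    alloc = rng.multinomial(n_reads, weights / weights.sum())

    positions: Dict[str, List[np.ndarray]] = {c: [] for c in chrom_sizes}
    for c, arr in _uniform_positions(rng, int(alloc[0]), chrom_sizes).items():
        positions[c].append(arr)
    for (iv, _), k in zip(enriched, alloc[1:]):
        if k:
            positions[iv.chrom].append(
                rng.integers(iv.start, iv.end, size=int(k)))

    lib = TagLibrary(
        {c: (np.concatenate(parts) if parts else np.array([], dtype=np.int64))
         for c, parts in positions.items()},
        label=label)
    if truth is not None and not control and mode == "gene_body":
        truth.hotspot_intervals.setdefault(condition, [])
        truth.hotspot_intervals[condition] = [(iv, f) for iv, f in enriched]
    return lib


# ---------------------------------------------------------------------------
# sequence

def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=probs)


def _rlfs_cassette(rng: np.random.Generator) -> str:
    """G-cluster initiation zone, A linker, G-rich elongation tail.

    Tail blocks carry exactly 60 G per 100 nt so the elongation-zone
    criterion (>= 40% G per 100-nt step) holds deterministically.
    """
    parts = [_RIZ_CASSETTE, _RLFS_LINKER]
    for _ in range(_RLFS_TAIL_BLOCKS):
        block = np.array(list("G" * _RLFS_TAIL_G_PER_BLOCK
                              + "ATC" * 13 + "A"), dtype="U1")
        rng.shuffle(block)
        parts.append("".join(block))
    return "".join(parts)


def generate_sequence(
    spec: GenomeSpec,
    genes: Sequence[SimGene],
    plant_rlfs_in: Optional[Iterable[str]] = None,
    seed: Optional[int] = None,
    truth: Optional[SimTruth] = None,
) -> Dict[str, str]:
    """I.i.d. background sequence with R-loop cassettes planted in genes.

    ``plant_rlfs_in`` names the target genes (defaults to those flagged
    ``planted_rlfs``); each receives one cassette on its coding strand at a
    random recorded offset. Minus-strand genes get the reverse complement
    on the plus strand so the cassette reads sense in transcription
    direction.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    gene_by_id = {g.gene_id: g for g in genes}
    if plant_rlfs_in is None:
        targets = [g for g in genes if g.planted_rlfs]
    else:
        missing = [gid for gid in plant_rlfs_in if gid not in gene_by_id]
        if missing:
            raise ValueError(f"unknown genes in plant set: {missing}")
        targets = [gene_by_id[gid] for gid in plant_rlfs_in]

    arrays = {c: _random_bases(rng, size, spec.gc_background)
              for c, size in spec.chrom_sizes.items()}
    for g in targets:
        cassette = _rlfs_cassette(rng)
        if g.strand == "-":
            cassette = _revcomp(cassette)
        span = g.interval.length - len(cassette)
        if span <= 0:
            continue  # gene too short to host a cassette
        off = g.interval.start + int(rng.integers(0, span))
        arr = arrays[g.interval.chrom]
        arr[off:off + len(cassette)] = \
            np.frombuffer(cassette.encode(), dtype="S1")
        if truth is not None:
            truth.rlfs_intervals.append(
                GenomicInterval(g.interval.chrom, off, off + len(cassette),
                                g.strand))
    return {c: arr.tobytes().decode() for c, arr in arrays.items()}


# ---------------------------------------------------------------------------
# whole-study convenience

def simulate_study(
    spec: Optional[GenomeSpec] = None,
    n_genes: int = 300,
    n_reads: int = 5_000_000,
    enrichment: float = 5.0,
    expression_coef: float = 0.5,
    length_range: Tuple[int, int] = (2_000, 100_000),
    max_dist: int = 10_000,
    n_hotspot: int = 30,
    seed: int = 0,
    with_sequence: bool = True,
    with_h3k27ac: bool = True,
) -> SimStudy:
    """Generate a full study: annotation, expression, libraries, sequence.

    Libraries: ``chip_A``/``chip_B`` (damage mark under the two oncogene
    conditions), ``control`` (uniform isotype), and optionally ``h3k27ac``
    (promoter-restricted active mark).
    """
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=8)]
    spec = spec or GenomeSpec(seed=seed)
    truth = SimTruth(params=dict(n_genes=n_genes, n_reads=n_reads,
                                 enrichment=enrichment,
                                 expression_coef=expression_coef, seed=seed))
    genes = generate_annotation(spec, n_genes=n_genes,
                                length_range=length_range, max_dist=max_dist,
                                n_hotspot=n_hotspot, seed=sub[0])
    expr = simulate_expression(genes, seed=sub[1])
    libs = {
        "chip_A": simulate_tags(genes, expr, n_reads, spec.chrom_sizes,
                                enrichment=enrichment,
                                expression_coef=expression_coef,
                                condition="A", seed=sub[2], truth=truth),
        "chip_B": simulate_tags(genes, expr, n_reads, spec.chrom_sizes,
                                enrichment=enrichment,
                                expression_coef=expression_coef,
                                condition="B", seed=sub[3], truth=truth),
        "control": simulate_tags(genes, expr, n_reads, spec.chrom_sizes,
                                 control=True, seed=sub[4]),
    }
    if with_h3k27ac:
        libs["h3k27ac"] = simulate_tags(
            genes, expr, n_reads, spec.chrom_sizes, enrichment=enrichment,
            expression_coef=expression_coef, condition="A", mode="promoter",
            promoter_body_fraction=0.2, seed=sub[5], truth=truth)
    sequences = (generate_sequence(spec, genes, seed=sub[6], truth=truth)
                 if with_sequence else {})
    return SimStudy(spec=spec, genes=genes, expression=expr, libraries=libs,
                    sequences=sequences, truth=truth)


def write_fixture(study: SimStudy, outdir) -> Dict[str, str]:
    """Write every study artifact as plain text; returns a path manifest."""
    from pathlib import Path

    from . import io as gio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, str] = {}

    models = [g.to_gene_model() for g in study.genes]
    gio.write_gtf(models, outdir / "annotation.gtf")
    gio.write_bed12(models, outdir / "annotation.bed12")
    paths["annotation_gtf"] = str(outdir / "annotation.gtf")
    paths["annotation_bed12"] = str(outdir / "annotation.bed12")

    gio.write_expression_tsv(study.expression, outdir / "expression.tsv")
    paths["expression"] = str(outdir / "expression.tsv")

    for name, lib in study.libraries.items():
        p = outdir / f"tags_{name}.bed"
        gio.write_tags_bed(lib, p)
        paths[f"tags_{name}"] = str(p)

    if study.sequences:
        gio.write_fasta(study.sequences, outdir / "genome.fa")
        paths["genome_fasta"] = str(outdir / "genome.fa")

    rows = []
    for cond, ivs in study.truth.hotspot_intervals.items():
        for iv, f in ivs:
            rows.append(dict(kind="hotspot", condition=cond, chrom=iv.chrom,
                             start=iv.start, end=iv.end, factor=f))
    for iv in study.truth.rlfs_intervals:
        rows.append(dict(kind="rlfs", condition=".", chrom=iv.chrom,
                         start=iv.start, end=iv.end, factor=float("nan")))
    pd.DataFrame(rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    paths["truth"] = str(outdir / "truth.tsv")

    meta = pd.DataFrame([
        dict(gene_id=g.gene_id, orientation_class=g.orientation_class,
             lineage_tag=g.lineage_tag, planted_hotspot=g.planted_hotspot,
             hotspot_conditions=",".join(sorted(g.hotspot_conditions)) or ".",
             planted_rlfs=g.planted_rlfs)
        for g in study.genes])
    meta.to_csv(outdir / "gene_truth.tsv", sep="\t", index=False)
    paths["gene_truth"] = str(outdir / "gene_truth.tsv")
    return paths
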