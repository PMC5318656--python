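"""Core coordinate and signal containers shared by every analysis stage.

All coordinates are 0-based, half-open ``[start, end)`` internally; GTF's
1-based inclusive convention is converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "TagLibrary",
    "WindowTrack",
    "GammaRegion",
    "GeneModel",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open, with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def sort_key(self) -> Tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class TagLibrary:
    """A ChIP tag library: per-chromosome sorted 5' read positions.

    Reads are single-bp positions; all downstream statistics operate on
    binned or interval counts, so no fragment model is kept.
    """

    def __init__(self, positions: Mapping[str, Iterable[int]], label: str = ""):
        self.positions: Dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            arr = np.asarray(list(pos) if not isinstance(pos, np.ndarray) else pos,
                             dtype=np.int64)
            self.positions[chrom] = np.sort(arr)
        self.label = label

    @property
    def total(self) -> int:
        return int(sum(len(v) for v in self.positions.values()))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of tags with position in [start, end)."""
        pos = self.positions.get(chrom)
        if pos is None or len(pos) == 0:
            return 0
        return int(np.searchsorted(pos, end, side="left")
                   - np.searchsorted(pos, start, side="left"))

    def count_interval(self, iv: GenomicInterval) -> int:
        return self.count_in(iv.chrom, iv.start, iv.end)

    def chroms(self) -> Tuple[str, ...]:
        return tuple(self.positions.keys())


@dataclass
class WindowTrack:
    """Fixed-width window counts of a tag library over a genome.

    ``lambda_bg`` is the uniform-background expectation per window used by
    the island caller's Poisson eligibility test.
    """

    window: int
    counts: Dict[str, np.ndarray]
    chrom_sizes: Dict[str, int]
    total: int

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    @property
    def lambda_bg(self) -> float:
        g = self.genome_length
        return self.total * self.window / g if g else 0.0


@dataclass
class GammaRegion:
    """A called gamma-H2AX-enriched region with its normalized signal metrics.

    nrpm is background-subtracted RPM (chip minus control, each per-million
    of its own library); fc is the pseudocounted chip/control fold change
    after scaling control counts to the chip library size; rpkm is chip
    read density per kb per million chip reads.
    """

    interval: GenomicInterval
    chip_rpm: float = float("nan")
    ctrl_rpm: float = float("nan")
    nrpm: float = float("nan")
    fc: float = float("nan")
    rpkm: float = float("nan")
    score: float = float("nan")
    qvalue: float = float("nan")
    origin: frozenset = field(default_factory=frozenset)

    @property
    def is_common(self) -> bool:
        return {"A", "B"} <= set(self.origin)


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene with exon structure.

    The TSS is the first transcribed base (interval start on '+', end-1 on
    '-'); the TES is the last. Exons are sorted, non-overlapping and nested
    within the gene interval.
    """

    gene_id: str
    name: str
    interval: GenomicInterval
    strand: str
    exons: Tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be +/-: {self.strand!r}")
        prev_end = None
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"exon outside gene body: {self.gene_id}")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"exons overlap or unsorted: {self.gene_id}")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    @property
    def length(self) -> int:
        return self.interval.length
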