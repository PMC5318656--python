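"""Readers and writers for the plain-text formats used across the pipeline.

BED and bedGraph are 0-based half-open; GTF is 1-based inclusive and is
converted exactly at this boundary. Tag libraries travel as 6-column BED of
single-bp intervals.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GammaRegion, GeneModel, GenomicInterval, TagLibrary

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed input file; carries the 1-based offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# coordinate conversions

def gtf_to_internal(start_1based: int, end_inclusive: int) -> Tuple[int, int]:
    """GTF 1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_inclusive


def internal_to_gtf(start: int, end: int) -> Tuple[int, int]:
    """0-based half-open -> GTF 1-based inclusive."""
    return start + 1, end


# ---------------------------------------------------------------------------
# tag libraries (BED6, single-bp intervals)

def write_tags_bed(lib: TagLibrary, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(lib.positions):
            for p in lib.positions[chrom]:
                fh.write(f"{chrom}\t{p}\t{p + 1}\t{lib.label or 'tag'}\t0\t+\n")


def read_tags_bed(path: PathLike, label: str = "") -> TagLibrary:
    positions: Dict[str, List[int]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError("BED line needs >= 3 fields", i)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"non-integer coordinate: {exc}", i) from exc
            if end <= start:
                raise FormatError("end must exceed start", i)
            positions.setdefault(fields[0], []).append(start)
    return TagLibrary(positions, label=label)


# ---------------------------------------------------------------------------
# regions (BED6+ with signal columns)

REGION_EXTRA_COLS = ["chip_rpm", "ctrl_rpm", "nrpm", "fc", "rpkm", "score",
                     "qvalue", "origin"]


def write_regions_bed(regions: Sequence[GammaRegion], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\t"
                 + "\t".join(REGION_EXTRA_COLS) + "\n")
        for k, r in enumerate(regions):
            iv = r.interval
            origin = ",".join(sorted(r.origin)) or "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tregion_{k + 1}\t0\t.\t"
                f"{r.chip_rpm:.6g}\t{r.ctrl_rpm:.6g}\t{r.nrpm:.6g}\t"
                f"{r.fc:.6g}\t{r.rpkm:.6g}\t{r.score:.6g}\t{r.qvalue:.6g}\t"
                f"{origin}\n"
            )


def read_regions_bed(path: PathLike) -> List[GammaRegion]:
    regions: List[GammaRegion] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 14:
                raise FormatError("region BED needs 14 fields", i)
            origin = frozenset() if f[13] == "." else frozenset(f[13].split(","))
            regions.append(GammaRegion(
                interval=GenomicInterval(f[0], int(f[1]), int(f[2])),
                chip_rpm=float(f[6]), ctrl_rpm=float(f[7]), nrpm=float(f[8]),
                fc=float(f[9]), rpkm=float(f[10]), score=float(f[11]),
                qvalue=float(f[12]), origin=origin,
            ))
    return regions


# ---------------------------------------------------------------------------
# bedGraph

def write_bedgraph(track_counts: Dict[str, np.ndarray], window: int,
                   chrom_sizes: Dict[str, int], path: PathLike) -> None:
    """Write window counts as bedGraph, merging zero runs away."""
    with open(path, "w") as fh:
        for chrom in sorted(track_counts):
            counts = track_counts[chrom]
            size = chrom_sizes[chrom]
            for i, c in enumerate(counts):
                if c == 0:
                    continue
                start = i * window
                end = min(size, (i + 1) * window)
                fh.write(f"{chrom}\t{start}\t{end}\t{c}\n")


def read_bedgraph(path: PathLike) -> List[Tuple[str, int, int, float]]:
    """Read bedGraph; rejects overlapping intervals with the line number."""
    out: List[Tuple[str, int, int, float]] = []
    last_end: Dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise FormatError("bedGraph needs 4 fields", i)
            chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            if end <= start:
                raise FormatError("end must exceed start", i)
            if start < last_end.get(chrom, 0):
                raise FormatError("overlapping bedGraph intervals", i)
            last_end[chrom] = end
            out.append((chrom, start, end, value))
    return out


# ---------------------------------------------------------------------------
# gene models: GTF and BED12

def write_gtf(genes: Sequence[GeneModel], path: PathLike,
              source: str = "gammamap") -> None:
    with open(path, "w") as fh:
        for g in genes:
            s1, e1 = internal_to_gtf(g.interval.start, g.interval.end)
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.name}";'
            fh.write(f"{g.interval.chrom}\t{source}\tgene\t{s1}\t{e1}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            for ex in g.exons:
                xs, xe = internal_to_gtf(ex.start, ex.end)
                fh.write(f"{g.interval.chrom}\t{source}\texon\t{xs}\t{xe}\t.\t"
                         f"{g.strand}\t.\t{attrs}\n")


def _parse_gtf_attrs(attr_field: str, line: int) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            key, value = part.split(" ", 1)
        except ValueError as exc:
            raise FormatError(f"malformed GTF attribute {part!r}", line) from exc
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: PathLike) -> List[GeneModel]:
    """Read gene + exon features; exons attach to genes by gene_id."""
    gene_rows: Dict[str, dict] = {}
    exon_rows: Dict[str, List[GenomicInterval]] = {}
    order: List[str] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError("GTF needs 9 fields", i)
            chrom, _, feature, s1, e1, _, strand, _, attr = f
            try:
                start, end = gtf_to_internal(int(s1), int(e1))
            except ValueError as exc:
                raise FormatError(f"non-integer coordinate: {exc}", i) from exc
            attrs = _parse_gtf_attrs(attr, i)
            gid = attrs.get("gene_id")
            if gid is None:
                raise FormatError("missing gene_id attribute", i)
            if feature == "gene":
                gene_rows[gid] = dict(chrom=chrom, start=start, end=end,
                                      strand=strand,
                                      name=attrs.get("gene_name", gid))
                order.append(gid)
            elif feature == "exon":
                exon_rows.setdefault(gid, []).append(
                    GenomicInterval(chrom, start, end, strand))
    genes = []
    for gid in order:
        row = gene_rows[gid]
        exons = tuple(sorted(exon_rows.get(gid, []),
                             key=lambda iv: (iv.start, iv.end)))
        genes.append(GeneModel(
            gene_id=gid, name=row["name"],
            interval=GenomicInterval(row["chrom"], row["start"], row["end"],
                                     row["strand"]),
            strand=row["strand"], exons=exons))
    return genes


def write_bed12(genes: Sequence[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            exons = g.exons or (iv,)
            sizes = ",".join(str(e.length) for e in exons) + ","
            starts = ",".join(str(e.start - iv.start) for e in exons) + ","
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t"
                     f"{g.strand}\t{iv.start}\t{iv.end}\t0\t{len(exons)}\t"
                     f"{sizes}\t{starts}\n")


# ---------------------------------------------------------------------------
# FASTA / expression / generic tables

def write_fasta(sequences: Dict[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: PathLike) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_expression_tsv(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise FormatError("expression table needs a gene_id column")
    return df


def write_json(obj, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
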