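"""R-loop-forming sequence (RLFS) prediction.

An RLFS is modeled as an R-loop initiation zone (RIZ: clustered G tracts,
overall >= 50% G), a short linker, and an elongation zone (REZ: a sustained
G-rich stretch read in fixed windows). Two models differ only in the
minimum G-tract length (m1: >= 3, m2: >= 4). Prediction runs on both
strands; a minus-strand hit is a plus-strand C-rich cassette read in
reverse complement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

from .core import GeneModel, GenomicInterval

__all__ = [
    "RlfsParams",
    "RLFSMatch",
    "find_rlfs",
    "find_rlfs_both_strands",
    "count_rlfs_per_gene",
]

_VALID = set("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class RlfsParams:
    """QmRLFS-style model constants; all exposed for reconciliation.

    tract_min_m1/m2: minimum G-run length per model.
    spacer_max: max non-G nucleotides between chained tracts inside a RIZ.
    riz_g_min: minimum G fraction over the whole RIZ span.
    linker_max: max distance (nt) from RIZ end to REZ start.
    rez_window: REZ step size; every step must be >= rez_g_min G.
    rez_search_max: REZ truncation distance downstream of its start.
    """

    tract_min_m1: int = 3
    tract_min_m2: int = 4
    spacer_max: int = 10
    riz_g_min: float = 0.5
    linker_max: int = 50
    rez_window: int = 100
    rez_g_min: float = 0.4
    rez_search_max: int = 2000


@dataclass(frozen=True)
class RLFSMatch:
    interval: GenomicInterval
    strand: str
    model_id: str
    riz: GenomicInterval
    riz_g_fraction: float
    linker_len: int
    rez: GenomicInterval
    rez_g_fraction: float


def _validate(seq: str) -> None:
    bad = set(seq.upper()) - _VALID
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")


def _g_tracts(seq: str, tract_min: int) -> List[Tuple[int, int]]:
    """Maximal runs of G with length >= tract_min, as (start, end)."""
    return [(m.start(), m.end())
            for m in re.finditer(f"G{{{tract_min},}}", seq)]


def _riz_candidates(seq: str, gcum: np.ndarray, tract_min: int,
                    params: RlfsParams) -> List[Tuple[int, int, float]]:
    """Maximal chains of >= 2 tracts with small non-G spacers, G-rich overall."""
    tracts = _g_tracts(seq, tract_min)
    out: List[Tuple[int, int, float]] = []
    i = 0
    while i < len(tracts):
        j = i
        while j + 1 < len(tracts):
            gap_s, gap_e = tracts[j][1], tracts[j + 1][0]
            non_g = (gap_e - gap_s) - int(gcum[gap_e] - gcum[gap_s])
            if non_g <= params.spacer_max:
                j += 1
            else:
                break
        if j > i:
            start, end = tracts[i][0], tracts[j][1]
            frac = (gcum[end] - gcum[start]) / (end - start)
            if frac >= params.riz_g_min:
                out.append((start, end, float(frac)))
        i = j + 1
    return out


def _best_rez(gcum: np.ndarray, seq_len: int, riz_end: int,
              params: RlfsParams) -> Optional[Tuple[int, int, int, float]]:
    """Longest REZ within linker reach: (linker, rez_start, rez_end, gfrac).

    For each linker offset, consecutive full windows qualify while each
    holds >= rez_g_min G and stays within rez_search_max of the REZ start;
    the longest REZ wins, ties to the shortest linker.
    """
    W = params.rez_window
    best: Optional[Tuple[int, int, int, float]] = None
    for d in range(params.linker_max + 1):
        s = riz_end + d
        w = 0
        while True:
            a = s + w * W
            b = a + W
            if b > seq_len or b - s > params.rez_search_max:
                break
            if (gcum[b] - gcum[a]) / W < params.rez_g_min:
                break
            w += 1
        if w > 0 and (best is None or w > best[0]):
            best = (w, d, s, 0.0)
    if best is None:
        return None
    w, d, s, _ = best
    frac = float((gcum[s + w * W] - gcum[s]) / (w * W))
    return d, s, s + w * W, frac


def _merge_matches(matches: List[RLFSMatch]) -> List[RLFSMatch]:
    """Union of overlapping same-model matches (keeps first RIZ, last REZ)."""
    out: List[RLFSMatch] = []
    for m in sorted(matches, key=lambda m: (m.model_id, m.interval.start,
                                            m.interval.end)):
        if (out and out[-1].model_id == m.model_id
                and m.interval.start < out[-1].interval.end
                and m.interval.chrom == out[-1].interval.chrom):
            prev = out[-1]
            out[-1] = RLFSMatch(
                interval=GenomicInterval(prev.interval.chrom,
                                         prev.interval.start,
                                         max(prev.interval.end, m.interval.end),
                                         prev.strand),
                strand=prev.strand, model_id=prev.model_id,
                riz=prev.riz, riz_g_fraction=prev.riz_g_fraction,
                linker_len=prev.linker_len,
                rez=m.rez if m.rez.end > prev.rez.end else prev.rez,
                rez_g_fraction=(m.rez_g_fraction if m.rez.end > prev.rez.end
                                else prev.rez_g_fraction))
        else:
            out.append(m)
    return out


def find_rlfs(seq: str, params: RlfsParams = RlfsParams(),
              chrom: str = "seq", strand: str = "+", offset: int = 0,
              merge: bool = True) -> List[RLFSMatch]:
    """Scan the given (plus) strand for RIZ-linker-REZ matches.

    ``offset`` shifts reported coordinates (for scanning sub-sequences);
    with ``merge`` overlapping same-model matches fuse to their union.
    """
    seq = seq.upper()
    _validate(seq)
    gcum = np.concatenate(([0], np.cumsum(np.frombuffer(
        seq.encode(), dtype="S1") == b"G")))
    matches: List[RLFSMatch] = []
    for model_id, tract_min in (("m1", params.tract_min_m1),
                                ("m2", params.tract_min_m2)):
        for riz_s, riz_e, riz_frac in _riz_candidates(seq, gcum, tract_min,
                                                      params):
            rez = _best_rez(gcum, len(seq), riz_e, params)
            if rez is None:
                continue
            linker, rez_s, rez_e, rez_frac = rez
            matches.append(RLFSMatch(
                interval=GenomicInterval(chrom, offset + riz_s,
                                         offset + rez_e, strand),
                strand=strand, model_id=model_id,
                riz=GenomicInterval(chrom, offset + riz_s, offset + riz_e,
                                    strand),
                riz_g_fraction=riz_frac, linker_len=linker,
                rez=GenomicInterval(chrom, offset + rez_s, offset + rez_e,
                                    strand),
                rez_g_fraction=rez_frac))
    return _merge_matches(matches) if merge else matches


def find_rlfs_both_strands(seq: str, params: RlfsParams = RlfsParams(),
                           chrom: str = "seq", merge: bool = True
                           ) -> List[RLFSMatch]:
    """Scan plus strand and the reverse complement, mapping coordinates back."""
    plus = find_rlfs(seq, params, chrom=chrom, strand="+", merge=merge)
    L = len(seq)
    rc = seq.upper().translate(_COMP)[::-1]
    minus: List[RLFSMatch] = []
    for m in find_rlfs(rc, params, chrom=chrom, strand="-", merge=merge):
        def flip(iv: GenomicInterval) -> GenomicInterval:
            return GenomicInterval(chrom, L - iv.end, L - iv.start, "-")
        minus.append(RLFSMatch(
            interval=flip(m.interval), strand="-", model_id=m.model_id,
            riz=flip(m.riz), riz_g_fraction=m.riz_g_fraction,
            linker_len=m.linker_len, rez=flip(m.rez),
            rez_g_fraction=m.rez_g_fraction))
    return plus + sorted(minus, key=lambda m: (m.model_id, m.interval.start))


def count_rlfs_per_gene(matches: Sequence[RLFSMatch],
                        genes: Sequence[GeneModel]) -> Dict[str, int]:
    """Strand-blind count of matches intersecting each gene span.

    A match spanning two genes increments both.
    """
    trees: Dict[str, IntervalTree] = {}
    for i, m in enumerate(matches):
        # carry an index so coincident intervals keep their multiplicity
        trees.setdefault(m.interval.chrom, IntervalTree()).addi(
            m.interval.start, m.interval.end, i)
    counts: Dict[str, int] = {}
    for g in genes:
        tree = trees.get(g.interval.chrom)
        counts[g.gene_id] = (len(tree.overlap(g.interval.start,
                                              g.interval.end))
                             if tree else 0)
    return counts
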