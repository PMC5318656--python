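"""Neighborhood transcription-orientation classes and their damage profiles.

Every gene is classified by its relation to its nearest neighbor within a
distance cutoff: overlapping, isolated, tandem (same direction), convergent
(3' ends facing) or divergent (5' ends facing). Convergent/divergent
neighborhoods expose single-stranded DNA between colliding or departing
polymerases and are candidate drivers of transcription-associated damage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, TagLibrary

__all__ = [
    "PairClassification",
    "ORIENTATION_CLASSES",
    "classify_gene_pairs",
    "category_fc_profiles",
]

ORIENTATION_CLASSES = ("overlapping", "isolated", "tandem", "convergent",
                       "divergent")


@dataclass(frozen=True)
class PairClassification:
    gene_id: str
    category: str
    partner_id: Optional[str]
    gap_bp: int


def _pair_category(left: GeneModel, right: GeneModel) -> str:
    """Orientation of a non-overlapping pair, left.start <= right.start."""
    if left.strand == right.strand:
        return "tandem"
    # + gene upstream (left) of - gene: 3' ends face each other
    return "convergent" if left.strand == "+" else "divergent"


def classify_gene_pairs(genes: Sequence[GeneModel], max_dist: int = 10_000,
                        ) -> List[PairClassification]:
    """Classify each gene against its neighborhood.

    Overlap with any gene takes precedence; otherwise a gene with no
    neighbor within ``max_dist`` (end-to-start gap) is isolated; otherwise
    the nearest neighbor decides tandem/convergent/divergent, with ties
    broken toward the neighbor on the right (larger coordinate).
    """
    by_chrom: Dict[str, List[Tuple[int, GeneModel]]] = {}
    for i, g in enumerate(genes):
        by_chrom.setdefault(g.interval.chrom, []).append((i, g))
    out: List[Optional[PairClassification]] = [None] * len(genes)

    for chrom, items in by_chrom.items():
        items.sort(key=lambda t: (t[1].interval.start, t[1].interval.end))
        n = len(items)
        for k, (i, g) in enumerate(items):
            overlap_partner = None
            for j, other in items:
                if j != i and g.interval.overlaps(other.interval):
                    overlap_partner = other
                    break
            if overlap_partner is not None:
                out[i] = PairClassification(g.gene_id, "overlapping",
                                            overlap_partner.gene_id, 0)
                continue
            best: Optional[Tuple[int, GeneModel, bool]] = None  # gap, gene, right?
            for j, other in items:
                if j == i:
                    continue
                if other.interval.start >= g.interval.end:
                    gap, right = other.interval.start - g.interval.end, True
                elif other.interval.end <= g.interval.start:
                    gap, right = g.interval.start - other.interval.end, False
                else:
                    continue  # overlapping neighbors handled above
                if (best is None or gap < best[0]
                        or (gap == best[0] and right and not best[2])):
                    best = (gap, other, right)
            if best is None or best[0] > max_dist:
                out[i] = PairClassification(g.gene_id, "isolated", None, 0)
                continue
            gap, partner, right = best
            left, rgt = (g, partner) if right else (partner, g)
            out[i] = PairClassification(g.gene_id, _pair_category(left, rgt),
                                        partner.gene_id, gap)
    return [c for c in out if c is not None]


def category_fc_profiles(genes: Sequence[GeneModel],
                         classifications: Sequence[PairClassification],
                         chip: TagLibrary, ctrl: TagLibrary,
                         n_bins: int = 40, eps: float = 0.1,
                         comparisons: Sequence[Tuple[str, str]] = (
                             ("convergent", "tandem"),
                             ("divergent", "tandem")),
                         ) -> Dict:
    """Length-normalized chip/control fold-change profiles per orientation.

    Each gene body is cut into ``n_bins`` equal fractions; per-bin FC is
    the pseudocounted RPM ratio chip/control; the per-gene summary is the
    mean FC over bins and category profiles average per-bin FC across
    member genes. Requested category pairs are compared on per-gene
    summaries with a two-sided Mann-Whitney U test.
    """
    cat_of = {c.gene_id: c.category for c in classifications}
    per_gene: Dict[str, List[float]] = {c: [] for c in ORIENTATION_CLASSES}
    profiles: Dict[str, np.ndarray] = {c: np.zeros(n_bins)
                                       for c in ORIENTATION_CLASSES}
    counts: Dict[str, int] = {c: 0 for c in ORIENTATION_CLASSES}

    for g in genes:
        cat = cat_of.get(g.gene_id)
        if cat is None or g.length < n_bins:
            continue
        edges = np.round(np.linspace(g.interval.start, g.interval.end,
                                     n_bins + 1)).astype(np.int64)
        pos_c = chip.positions.get(g.interval.chrom,
                                   np.array([], dtype=np.int64))
        pos_k = ctrl.positions.get(g.interval.chrom,
                                   np.array([], dtype=np.int64))
        cc = np.diff(np.searchsorted(pos_c, edges)) * 1e6 / chip.total
        kk = np.diff(np.searchsorted(pos_k, edges)) * 1e6 / ctrl.total
        fc = (cc + eps) / (kk + eps)
        if g.strand == "-":
            fc = fc[::-1]
        profiles[cat] += fc
        counts[cat] += 1
        per_gene[cat].append(float(fc.mean()))

    for c in ORIENTATION_CLASSES:
        if counts[c]:
            profiles[c] /= counts[c]

    tests = {}
    for a, b in comparisons:
        if not per_gene[a] or not per_gene[b]:
            raise ValueError(f"empty category in comparison {a} vs {b}")
        res = stats.mannwhitneyu(per_gene[a], per_gene[b],
                                 alternative="two-sided", method="asymptotic")
        tests[f"{a}_vs_{b}"] = dict(u_statistic=float(res.statistic),
                                    p_value=float(res.pvalue),
                                    n=(len(per_gene[a]), len(per_gene[b])))
    return dict(profiles=profiles, per_gene_fc=per_gene, n_genes=counts,
                tests=tests)
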