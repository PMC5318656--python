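"""Permutation and contingency machinery for region/gene enrichment claims.

Empirical p-values use the add-one rule (1 + #null at least as extreme) /
(N + 1), so they are never zero. The gene-sampling null redraws equally
sized gene sets from the population; the region-shuffling null re-places
every query region at a random genomic location preserving its length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import GenomicInterval

__all__ = [
    "PermutationResult",
    "ContingencyResult",
    "empirical_p",
    "permute_gene_sample",
    "permute_region_overlap",
    "RegionOverlapResult",
    "contingency_enrichment",
]


@dataclass
class PermutationResult:
    observed: float
    null_values: np.ndarray
    n_perm: int
    empirical_p: float
    tail: str
    seed: Optional[int] = None

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1)) \
            if len(self.null_values) > 1 else 0.0


def empirical_p(observed: float, null_values: Sequence[float],
                tail: str = "greater") -> float:
    """Add-one empirical p-value; 'greater' counts null >= observed."""
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    if tail == "greater":
        k = int(np.sum(null >= observed))
    elif tail == "less":
        k = int(np.sum(null <= observed))
    elif tail == "two-sided":
        center = float(np.mean(null))
        k = int(np.sum(np.abs(null - center) >= abs(observed - center)))
    else:
        raise ValueError(f"unknown tail: {tail!r}")
    return (1 + k) / (null.size + 1)


def permute_gene_sample(gene_stat: Mapping[str, float],
                        target_set: Sequence[str],
                        population: Sequence[str],
                        n_perm: int = 10_000,
                        seed: int = 0,
                        restrict_to: Optional[Sequence[str]] = None,
                        exhaustive: bool = False) -> PermutationResult:
    """Gene-sampling null for a summed per-gene statistic.

    The observed value is the statistic summed over the target genes; each
    permutation redraws the same number of genes uniformly without
    replacement from the population and sums. With ``restrict_to`` both
    target and population intersect a subset first (e.g. the most highly
    expressed genes). ``exhaustive`` enumerates all possible draws when
    their number does not exceed ``n_perm``.
    """
    population = list(dict.fromkeys(population))
    target = list(dict.fromkeys(target_set))
    if restrict_to is not None:
        allowed = set(restrict_to)
        population = [g for g in population if g in allowed]
        target = [g for g in target if g in allowed]
    if not set(target) <= set(population):
        raise ValueError("target set must be contained in the population")
    if len(target) > len(population):
        raise ValueError("target larger than population")
    if len(target) == 0:
        raise ValueError("target set empty after restriction")

    values = np.array([float(gene_stat.get(g, 0.0)) for g in population])
    t_idx = [population.index(g) for g in target]
    observed = float(values[t_idx].sum())
    k = len(target)

    if exhaustive and comb(len(population), k) <= n_perm:
        null = np.array([values[list(c)].sum()
                         for c in combinations(range(len(population)), k)])
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = values[rng.choice(len(values), size=k,
                                        replace=False)].sum()
    p = empirical_p(observed, null, "greater")
    return PermutationResult(observed=observed, null_values=null,
                             n_perm=len(null), empirical_p=p, tail="greater",
                             seed=seed)


# ---------------------------------------------------------------------------
# region-shuffling overlap test

def _to_ivs(regions: Sequence) -> List[GenomicInterval]:
    return [r.interval if hasattr(r, "interval") else r for r in regions]


def _overlap_counts(q_chrom: np.ndarray, q_start: np.ndarray,
                    q_end: np.ndarray, t_chrom: np.ndarray,
                    t_start: np.ndarray, t_end: np.ndarray
                    ) -> Tuple[int, int]:
    """(# targets hit by >=1 query, # queries hitting >=1 target)."""
    t_hit = np.zeros(len(t_start), dtype=bool)
    q_hit = np.zeros(len(q_start), dtype=bool)
    for c in np.unique(q_chrom):
        qm = q_chrom == c
        tm = t_chrom == c
        if not tm.any():
            continue
        ov = (q_start[qm][:, None] < t_end[tm][None, :]) & \
             (t_start[tm][None, :] < q_end[qm][:, None])
        q_hit[qm] |= ov.any(axis=1)
        t_hit[tm] |= ov.any(axis=0)
    return int(t_hit.sum()), int(q_hit.sum())


@dataclass
class RegionOverlapResult:
    """Both directions of a region-shuffling overlap permutation test."""

    targets_hit: PermutationResult
    queries_hit: PermutationResult
    pct_targets_overlapping: float
    pct_queries_overlapping: float
    n_queries: int
    n_targets: int


def permute_region_overlap(query_regions: Sequence,
                           target_regions: Sequence,
                           chrom_sizes: Mapping[str, int],
                           n_perm: int = 10_000,
                           seed: int = 0,
                           strategy: str = "genome") -> RegionOverlapResult:
    """Length-preserving random re-placement null for interval overlap.

    Each permutation re-places every query region at a uniform random
    start, on a length-weighted random chromosome ("genome" strategy) or
    on its own chromosome ("same-chrom"). Overlap is >= 1 bp; the test is
    one-sided for enrichment in both directions (targets hit by queries,
    queries hitting targets).
    """
    if strategy not in ("genome", "same-chrom"):
        raise ValueError(f"unknown strategy: {strategy!r}")
    queries = _to_ivs(query_regions)
    targets = _to_ivs(target_regions)
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    chrom_code = {c: i for i, c in enumerate(chroms)}

    q_len = np.array([iv.length for iv in queries], dtype=np.int64)
    for iv in queries:
        if not np.any(sizes >= iv.length):
            raise ValueError(f"query region longer than every chromosome: "
                             f"{iv.length} bp")
    q_chrom0 = np.array([chrom_code[iv.chrom] for iv in queries])
    q_start0 = np.array([iv.start for iv in queries], dtype=np.int64)
    t_chrom = np.array([chrom_code[iv.chrom] for iv in targets]) \
        if targets else np.array([], dtype=int)
    t_start = np.array([iv.start for iv in targets], dtype=np.int64)
    t_end = np.array([iv.end for iv in targets], dtype=np.int64)

    obs_t, obs_q = _overlap_counts(q_chrom0, q_start0, q_start0 + q_len,
                                   t_chrom, t_start, t_end)

    rng = np.random.default_rng(seed)
    probs = sizes / sizes.sum()
    null_t = np.empty(n_perm)
    null_q = np.empty(n_perm)
    nq = len(queries)
    for i in range(n_perm):
        if strategy == "genome":
            cc = rng.choice(len(chroms), size=nq, p=probs)
            # redraw chromosomes too small for a given region
            bad = sizes[cc] < q_len
            while bad.any():
                cc[bad] = rng.choice(len(chroms), size=int(bad.sum()), p=probs)
                bad = sizes[cc] < q_len
        else:
            cc = q_chrom0
        starts = (rng.random(nq) * (sizes[cc] - q_len + 1)).astype(np.int64)
        null_t[i], null_q[i] = _overlap_counts(cc, starts, starts + q_len,
                                               t_chrom, t_start, t_end)

    res_t = PermutationResult(observed=obs_t, null_values=null_t,
                              n_perm=n_perm,
                              empirical_p=empirical_p(obs_t, null_t),
                              tail="greater", seed=seed)
    res_q = PermutationResult(observed=obs_q, null_values=null_q,
                              n_perm=n_perm,
                              empirical_p=empirical_p(obs_q, null_q),
                              tail="greater", seed=seed)
    return RegionOverlapResult(
        targets_hit=res_t, queries_hit=res_q,
        pct_targets_overlapping=100.0 * obs_t / len(targets) if targets else 0.0,
        pct_queries_overlapping=100.0 * obs_q / nq if nq else 0.0,
        n_queries=nq, n_targets=len(targets))


# ---------------------------------------------------------------------------
# contingency

@dataclass
class ContingencyResult:
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: float
    p_value: float


def contingency_enrichment(overlap: int, set_a_size: int, set_b_size: int,
                           universe_size: int) -> ContingencyResult:
    """Two-by-two Fisher exact enrichment of two gene sets in a universe.

    Table: [[A∩B, A\\B], [B\\A, universe - A∪B]]. Two-sided p by summing
    tables with probability <= the observed table's. The odds ratio gets
    the Haldane 0.5 correction when any cell is zero.
    """
    if overlap > min(set_a_size, set_b_size):
        raise ValueError("overlap exceeds a set size")
    if max(set_a_size, set_b_size) > universe_size:
        raise ValueError("set larger than universe")
    a = overlap
    b = set_a_size - overlap
    c = set_b_size - overlap
    d = universe_size - set_a_size - set_b_size + overlap
    if d < 0:
        raise ValueError("inconsistent inputs: negative derived cell")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if 0 in (a, b, c, d):
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return ContingencyResult(table=((a, b), (c, d)), odds_ratio=float(orr),
                             p_value=float(p))
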