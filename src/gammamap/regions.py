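"""Broad-domain island calling and region normalization.

The caller follows the SICER scheme adapted for broad damage marks: tag
libraries are binned into fixed windows, windows are scored against a
genome-wide Poisson background, runs of eligible windows tolerating small
gaps fuse into islands, and every island is then tested against the
isotype/input control with a library-size-scaled Poisson test and
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import GammaRegion, GenomicInterval, TagLibrary, WindowTrack

__all__ = [
    "IslandParams",
    "MergedRegion",
    "bin_tags",
    "rpm",
    "call_islands",
    "normalize_region",
    "merge_region_lists",
    "rank_regions",
    "condition_specific_regions",
]


@dataclass(frozen=True)
class IslandParams:
    """Tuning of the island caller.

    window: bin width in bp (broad marks need kb-scale windows).
    gap: maximum run of ineligible windows bridged inside one island.
    p0: Poisson upper-tail eligibility threshold per window.
    fc_min / fdr_max: retention filters on the island-level control test.
    pseudo: pseudocount (tags) protecting ratios against empty controls.
    """

    window: int = 1000
    gap: int = 3
    p0: float = 0.01
    fc_min: float = 2.0
    fdr_max: float = 0.01
    pseudo: float = 1.0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1 bp")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must be in (0, 1)")
        if self.fc_min <= 0 or not 0 < self.fdr_max <= 1:
            raise ValueError("fc_min > 0 and 0 < fdr_max <= 1 required")


def bin_tags(lib: TagLibrary, window: int, chrom_sizes: Dict[str, int]) -> WindowTrack:
    """Count tags per fixed window; the last partial window is kept.

    Window i on a chromosome covers [i*W, (i+1)*W); a tag at position p
    lands in window p // W.
    """
    if window < 1:
        raise ValueError("window must be >= 1 bp")
    counts: Dict[str, np.ndarray] = {}
    total = 0
    for chrom, size in chrom_sizes.items():
        n_win = (size + window - 1) // window
        pos = lib.positions.get(chrom)
        if pos is None or len(pos) == 0:
            counts[chrom] = np.zeros(n_win, dtype=np.int64)
            continue
        if pos[0] < 0 or pos[-1] >= size:
            raise ValueError(f"tag positions outside {chrom} bounds")
        counts[chrom] = np.bincount(pos // window, minlength=n_win).astype(np.int64)
        total += len(pos)
    return WindowTrack(window=window, counts=counts, chrom_sizes=dict(chrom_sizes),
                       total=total)


def rpm(count: float, total: int) -> float:
    """Reads per million: count * 1e6 / library size."""
    if total <= 0:
        raise ValueError("library total must be > 0 for RPM")
    return count * 1e6 / total


def _eligible(counts: np.ndarray, lam: float, p0: float) -> np.ndarray:
    # Upper-tail P(X >= count) = sf(count - 1); count 0 is never eligible
    # under a positive background.
    pvals = stats.poisson.sf(counts - 1, lam)
    return (pvals < p0) & (counts > 0)


def _island_spans(eligible: np.ndarray, gap: int) -> List[Tuple[int, int]]:
    """Fuse runs of eligible windows separated by <= gap ineligible ones.

    Returns inclusive (first, last) eligible-window indices per island.
    """
    idx = np.flatnonzero(eligible)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > gap + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def region_metrics(chip_count: int, ctrl_count: int, chip_total: int,
                   ctrl_total: int, length: int, pseudo: float = 1.0,
                   ) -> Tuple[float, float, float, float, float]:
    """(chip_rpm, ctrl_rpm, nrpm, fc, rpkm) for one interval.

    fc scales the control count by the library-size ratio before the
    pseudocounted ratio; nrpm may be negative by construction.
    """
    chip_rpm = rpm(chip_count, chip_total)
    ctrl_rpm = rpm(ctrl_count, ctrl_total)
    nrpm = chip_rpm - ctrl_rpm
    scaled_ctrl = ctrl_count * chip_total / ctrl_total
    fc = (chip_count + pseudo) / (scaled_ctrl + pseudo)
    rpkm = chip_count / ((length / 1000.0) * (chip_total / 1e6))
    return chip_rpm, ctrl_rpm, nrpm, fc, rpkm


def normalize_region(iv: GenomicInterval, chip: TagLibrary, ctrl: TagLibrary,
                     pseudo: float = 1.0) -> Tuple[float, float, float, float, float]:
    """Signal metrics for an arbitrary interval straight from the libraries."""
    return region_metrics(chip.count_interval(iv), ctrl.count_interval(iv),
                          chip.total, ctrl.total, iv.length, pseudo)


def call_islands(chip: WindowTrack, ctrl: WindowTrack,
                 params: IslandParams = IslandParams(),
                 origin: str = "") -> List[GammaRegion]:
    """Call control-filtered broad enrichment islands from window tracks.

    Stages: per-window Poisson eligibility against the chip library's
    uniform background; gap-tolerant fusion of eligible runs; island score
    as the sum of -ln(window p) over eligible members; a per-island Poisson
    test of the chip count with mean set by the size-scaled control count;
    BH correction across islands; retention at qvalue <= fdr_max and
    fc >= fc_min.
    """
    if chip.window != ctrl.window or chip.window != params.window:
        raise ValueError("chip/ctrl/params window sizes must agree")
    if set(chip.counts) != set(ctrl.counts):
        raise ValueError("chip and control tracks cover different chromosomes")
    if chip.chrom_sizes != ctrl.chrom_sizes:
        raise ValueError("chip and control chromosome sizes differ")

    lam = chip.lambda_bg
    W = params.window
    candidates: List[dict] = []
    for chrom in sorted(chip.counts):
        counts = chip.counts[chrom]
        elig = _eligible(counts, lam, params.p0)
        for first, last in _island_spans(elig, params.gap):
            start = first * W
            end = min(chip.chrom_sizes[chrom], (last + 1) * W)
            member = np.arange(first, last + 1)
            emask = elig[first:last + 1]
            with np.errstate(divide="ignore"):
                logp = -stats.poisson.logsf(counts[member[emask]] - 1, lam)
            score = float(np.sum(logp))
            chip_count = int(counts[first:last + 1].sum())
            ctrl_count = int(ctrl.counts[chrom][first:last + 1].sum())
            candidates.append(dict(chrom=chrom, start=start, end=end,
                                   score=score, chip_count=chip_count,
                                   ctrl_count=ctrl_count))
    if not candidates:
        return []

    chip_total, ctrl_total = chip.total, ctrl.total
    pvals = np.empty(len(candidates))
    for i, c in enumerate(candidates):
        scaled = c["ctrl_count"] * chip_total / ctrl_total
        pvals[i] = stats.poisson.sf(c["chip_count"] - 1, scaled + params.pseudo)
    qvals = stats.false_discovery_control(pvals, method="bh")

    regions: List[GammaRegion] = []
    for c, q in zip(candidates, qvals):
        length = c["end"] - c["start"]
        chip_rpm_, ctrl_rpm_, nrpm, fc, rpkm_ = region_metrics(
            c["chip_count"], c["ctrl_count"], chip_total, ctrl_total,
            length, params.pseudo)
        if q <= params.fdr_max and fc >= params.fc_min:
            regions.append(GammaRegion(
                interval=GenomicInterval(c["chrom"], c["start"], c["end"]),
                chip_rpm=chip_rpm_, ctrl_rpm=ctrl_rpm_, nrpm=nrpm, fc=fc,
                rpkm=rpkm_, score=c["score"], qvalue=float(q),
                origin=frozenset({origin}) if origin else frozenset()))
    regions.sort(key=lambda r: r.interval.sort_key())
    return regions


# ---------------------------------------------------------------------------
# merging, ranking, condition specificity

@dataclass(frozen=True)
class MergedRegion:
    """A region from the union of two condition lists with origin labels."""

    interval: GenomicInterval
    origin: frozenset

    @property
    def is_common(self) -> bool:
        return {"A", "B"} <= set(self.origin)


def _is_sorted_disjoint(ivs: Sequence[GenomicInterval]) -> bool:
    for a, b in zip(ivs, ivs[1:]):
        if b.sort_key() < a.sort_key():
            return False
        if a.chrom == b.chrom and b.start < a.end:
            return False
    return True


def merge_region_lists(list_a: Sequence, list_b: Sequence,
                       label_a: str = "A", label_b: str = "B",
                       ) -> List[MergedRegion]:
    """Fuse two internally disjoint region lists into a labeled union.

    Overlapping or bookended intervals fuse; a merged region is labeled
    with every condition that contributed, hence "common" means both.
    Accepts GammaRegion, MergedRegion or bare GenomicInterval inputs.
    """
    def ivs_of(lst, label):
        out = []
        for r in lst:
            iv = r.interval if hasattr(r, "interval") else r
            labels = set(getattr(r, "origin", ()) or ()) or {label}
            out.append((iv, frozenset(labels)))
        return out

    items = ivs_of(list_a, label_a) + ivs_of(list_b, label_b)
    for lst, name in ((list_a, label_a), (list_b, label_b)):
        ivs = [r.interval if hasattr(r, "interval") else r for r in lst]
        if not _is_sorted_disjoint(ivs):
            warnings.warn(f"region list {name} unsorted or overlapping; "
                          "sorting internally", stacklevel=2)
    items.sort(key=lambda t: t[0].sort_key())

    merged: List[MergedRegion] = []
    cur_iv: Optional[GenomicInterval] = None
    cur_lab: set = set()
    for iv, labels in items:
        if cur_iv is not None and iv.chrom == cur_iv.chrom and iv.start <= cur_iv.end:
            cur_iv = GenomicInterval(cur_iv.chrom, cur_iv.start,
                                     max(cur_iv.end, iv.end))
            cur_lab |= set(labels)
        else:
            if cur_iv is not None:
                merged.append(MergedRegion(cur_iv, frozenset(cur_lab)))
            cur_iv, cur_lab = iv, set(labels)
    if cur_iv is not None:
        merged.append(MergedRegion(cur_iv, frozenset(cur_lab)))
    return merged


def rank_regions(regions: Sequence[GammaRegion],
                 region_genes: Sequence[Sequence[str]]):
    """Rank regions by fold change, collapsing regions that share a gene.

    Regions overlapping a common gene merge into one row carrying the
    arithmetic mean FC (and nRPM) of the members; ranking is descending FC
    with ties broken by nRPM then coordinate. Returns a pandas DataFrame.
    """
    import pandas as pd

    n = len(regions)
    if len(region_genes) != n:
        raise ValueError("region_genes must parallel regions")
    # union-find over regions sharing any gene
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_gene: Dict[str, int] = {}
    for i, genes in enumerate(region_genes):
        for g in genes:
            if g in by_gene:
                union(by_gene[g], i)
            else:
                by_gene[g] = i

    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    rows = []
    for members in groups.values():
        regs = [regions[i] for i in members]
        genes = sorted({g for i in members for g in region_genes[i]})
        first = min(regs, key=lambda r: r.interval.sort_key())
        rows.append(dict(
            genes=",".join(genes) if genes else ".",
            fc=float(np.mean([r.fc for r in regs])),
            nrpm=float(np.mean([r.nrpm for r in regs])),
            rpkm=float(np.mean([r.rpkm for r in regs])),
            n_regions=len(regs),
            chrom=first.interval.chrom, start=first.interval.start,
            end=max(r.interval.end for r in regs
                    if r.interval.chrom == first.interval.chrom),
        ))
    df = pd.DataFrame(rows)
    df = df.sort_values(["fc", "nrpm", "chrom", "start"],
                        ascending=[False, False, True, True],
                        kind="mergesort").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def condition_specific_regions(regions: Sequence, chip_a: TagLibrary,
                               chip_b: TagLibrary, ctrl: TagLibrary,
                               min_fc_ab: float = 2.0, eps: float = 1.0):
    """Regions whose damage signal is specific to condition A over B.

    Cross-condition FC = (nRPM_A + eps) / (nRPM_B + eps) with negative nRPM
    floored at zero; regions at or above min_fc_ab return sorted descending.
    Returns a DataFrame with both conditions' nRPM and the cross FC.
    """
    import pandas as pd

    rows = []
    for r in regions:
        iv = r.interval if hasattr(r, "interval") else r
        _, _, nrpm_a, _, _ = normalize_region(iv, chip_a, ctrl)
        _, _, nrpm_b, _, _ = normalize_region(iv, chip_b, ctrl)
        cross = (max(nrpm_a, 0.0) + eps) / (max(nrpm_b, 0.0) + eps)
        rows.append(dict(chrom=iv.chrom, start=iv.start, end=iv.end,
                         nrpm_a=nrpm_a, nrpm_b=nrpm_b, cross_fc=cross))
    df = pd.DataFrame(rows)
    if len(df) == 0:
        return df
    df = df[df.cross_fc >= min_fc_ab]
    return df.sort_values("cross_fc", ascending=False,
                          kind="mergesort").reset_index(drop=True)
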