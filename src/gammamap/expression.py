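"""Expression (FPKM) integration with damage signal and the H3K27ac mark.

High/low expression categories split expressed genes at their median FPKM;
category-wise damage comparison uses the Mann-Whitney U test; differential
expression is a transparent pseudocounted log2 fold-change call; signal
correlations are plain Pearson with a least-squares line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import extend_interval
from .core import GeneModel, GenomicInterval, TagLibrary
from .regions import normalize_region

__all__ = [
    "categorize_expression",
    "gene_signal",
    "category_signal_test",
    "differential_expression",
    "delta_signal_correlation",
    "h3k27ac_gamma_correlation",
]


def categorize_expression(table: pd.DataFrame, condition: str = "A",
                          expressed_min: float = 0.0) -> pd.DataFrame:
    """Label genes expressed/high/low relative to the expressed-gene median.

    A gene is expressed iff FPKM > ``expressed_min``; the median is taken
    over expressed genes only; FPKM above the median is "high", at or
    below it "low" (ties at the median fall to "low"). Non-expressed genes
    carry no category.
    """
    if len(table) == 0:
        raise ValueError("expression table is empty")
    col = f"fpkm_{condition}" if f"fpkm_{condition}" in table.columns else "fpkm"
    if col not in table.columns:
        raise KeyError(f"no FPKM column for condition {condition!r}")
    out = table[["gene_id", col]].rename(columns={col: "fpkm"}).copy()
    out["expressed"] = out.fpkm > expressed_min
    if not out.expressed.any():
        raise ValueError("no expressed genes; categories undefined")
    median = float(out.loc[out.expressed, "fpkm"].median())
    out["category"] = None
    out.loc[out.expressed, "category"] = np.where(
        out.loc[out.expressed, "fpkm"] > median, "high", "low")
    out.attrs["median_fpkm"] = median
    return out


def gene_signal(genes: Sequence[GeneModel], chip: TagLibrary,
                ctrl: TagLibrary, flank: int = 10_000,
                chrom_sizes: Optional[Mapping[str, int]] = None) -> pd.Series:
    """Background-subtracted RPM per gene over its flank-extended span."""
    vals = {}
    for g in genes:
        size = (chrom_sizes or {}).get(g.interval.chrom,
                                       g.interval.end + flank)
        ext = extend_interval(g.interval, flank, size)
        _, _, nrpm, _, _ = normalize_region(ext, chip, ctrl)
        vals[g.gene_id] = nrpm
    return pd.Series(vals, name="nrpm")


def category_signal_test(gene_nrpm: pd.Series, categories: pd.DataFrame,
                         ) -> Dict[str, float]:
    """Compare damage signal between high- and low-expression categories.

    Two-sided Mann-Whitney U with the normal approximation and tie
    correction. Also reports the share of genes falling in each category
    among the tested set (proportions sum to one).
    """
    cat = categories.set_index("gene_id")["category"]
    common = gene_nrpm.index.intersection(cat.dropna().index)
    hi = gene_nrpm[common[cat[common] == "high"]].to_numpy()
    lo = gene_nrpm[common[cat[common] == "low"]].to_numpy()
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("both expression categories must be non-empty")
    res = stats.mannwhitneyu(hi, lo, alternative="two-sided",
                             method="asymptotic")
    n = len(hi) + len(lo)
    return dict(u_statistic=float(res.statistic), p_value=float(res.pvalue),
                n_high=len(hi), n_low=len(lo),
                prop_high=len(hi) / n, prop_low=len(lo) / n,
                median_high=float(np.median(hi)),
                median_low=float(np.median(lo)))


def differential_expression(table: pd.DataFrame,
                            min_abs_log2fc: float = 1.0,
                            expressed_min: float = 0.0,
                            delta: float = 0.1) -> pd.DataFrame:
    """Pseudocounted log2 fold-change DE call between conditions A and B.

    A gene is DE iff it is expressed in at least one condition and
    |log2((fpkm_A + delta) / (fpkm_B + delta))| >= min_abs_log2fc;
    direction +1 means up in A.
    """
    out = table[["gene_id", "fpkm_A", "fpkm_B"]].copy()
    out["log2fc"] = np.log2((out.fpkm_A + delta) / (out.fpkm_B + delta))
    expressed = (out.fpkm_A > expressed_min) | (out.fpkm_B > expressed_min)
    out["de"] = expressed & (out.log2fc.abs() >= min_abs_log2fc)
    out["direction"] = np.where(out.de, np.sign(out.log2fc), 0).astype(int)
    return out


def delta_signal_correlation(gene_nrpm_a: pd.Series, gene_nrpm_b: pd.Series,
                             de_table: pd.DataFrame,
                             ) -> Tuple[float, float, float, pd.DataFrame]:
    """Pearson r of per-gene damage change vs expression log2 fold change.

    Returns (r, slope, intercept, table) over the shared gene universe;
    raises when either variable is constant.
    """
    df = de_table.set_index("gene_id")[["log2fc", "de", "direction"]].copy()
    common = df.index.intersection(gene_nrpm_a.index).intersection(
        gene_nrpm_b.index)
    if len(common) < 3:
        raise ValueError("need >= 3 shared genes for a correlation")
    df = df.loc[common]
    df["delta_nrpm"] = gene_nrpm_a[common] - gene_nrpm_b[common]
    if np.isclose(df.delta_nrpm.std(), 0) or np.isclose(df.log2fc.std(), 0):
        raise ValueError("zero variance; correlation undefined")
    r, _ = stats.pearsonr(df.log2fc, df.delta_nrpm)
    fit = stats.linregress(df.log2fc, df.delta_nrpm)
    return float(r), float(fit.slope), float(fit.intercept), df.reset_index()


def h3k27ac_gamma_correlation(regions: Sequence, gamma: TagLibrary,
                              h3k27ac: TagLibrary, ctrl: TagLibrary,
                              flank: int = 10_000,
                              chrom_sizes: Optional[Mapping[str, int]] = None,
                              ) -> Dict[str, float]:
    """Co-occurrence and correlation of damage and active-chromatin marks.

    Each flank-extended region gets a background-subtracted RPM for both
    marks; a region is positive for a mark iff its value exceeds zero. The
    Pearson r is computed on the double-positive subset only, alongside
    the double-positive fraction.
    """
    gvals, kvals = [], []
    for r in regions:
        iv = r.interval if hasattr(r, "interval") else r
        size = (chrom_sizes or {}).get(iv.chrom, iv.end + flank)
        ext = extend_interval(iv, flank, size)
        _, _, g_nrpm, _, _ = normalize_region(ext, gamma, ctrl)
        _, _, k_nrpm, _, _ = normalize_region(ext, h3k27ac, ctrl)
        gvals.append(g_nrpm)
        kvals.append(k_nrpm)
    gvals = np.asarray(gvals)
    kvals = np.asarray(kvals)
    both = (gvals > 0) & (kvals > 0)
    fraction = float(both.mean()) if len(both) else 0.0
    if both.sum() < 3:
        raise ValueError("fewer than 3 double-positive regions; r undefined")
    r, p = stats.pearsonr(gvals[both], kvals[both])
    return dict(fraction_double_positive=fraction, r=float(r),
                p_value=float(p), n_double_positive=int(both.sum()),
                n_regions=len(gvals))
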