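"""Validated pipeline configuration, loadable from a YAML key-value file."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, Optional

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with its documented range.

    Simulation block sizes the synthetic study; calling block drives the
    island caller; the remaining knobs parameterize annotation, expression
    integration, orientation, RLFS scanning and the permutation tests.
    """

    seed: int = 0
    outdir: str = "gammamap_out"

    # simulation
    chrom_sizes: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000})
    gc_background: float = 0.40
    n_genes: int = 300
    n_reads: int = 5_000_000
    enrichment: float = 5.0
    expression_coef: float = 0.5
    gene_length_min: int = 2_000
    gene_length_max: int = 100_000
    n_hotspot: int = 30
    with_sequence: bool = True
    with_h3k27ac: bool = True

    # island calling
    window: int = 1000
    gap: int = 3
    p0: float = 0.01
    fc_min: float = 2.0
    fdr_max: float = 0.01
    pseudo: float = 1.0

    # annotation / metagene
    flank: int = 10_000
    n_body_bins: int = 100
    flank_bin_bp: int = 500
    metagene_mode: str = "subtract"

    # expression
    expressed_min: float = 0.0
    min_abs_log2fc: float = 1.0
    de_delta: float = 0.1

    # orientation
    max_dist: int = 10_000
    orientation_bins: int = 40
    orientation_eps: float = 0.1

    # condition specificity
    min_fc_ab: float = 2.0
    specific_eps: float = 1.0

    # enrichment statistics
    n_perm: int = 10_000
    top_expressed: int = 1000
    overlap_strategy: str = "genome"

    def __post_init__(self) -> None:
        checks = [
            (self.seed >= 0, "seed must be >= 0"),
            (all(v > 0 for v in self.chrom_sizes.values()),
             "chromosome sizes must be > 0"),
            (0.0 <= self.gc_background <= 1.0, "gc_background in [0,1]"),
            (self.n_genes >= 1, "n_genes >= 1"),
            (self.n_reads >= 0, "n_reads >= 0"),
            (self.enrichment >= 1.0, "enrichment >= 1"),
            (0 < self.gene_length_min <= self.gene_length_max,
             "0 < gene_length_min <= gene_length_max"),
            (self.n_hotspot >= 0, "n_hotspot >= 0"),
            (self.window >= 1, "window >= 1"),
            (self.gap >= 0, "gap >= 0"),
            (0.0 < self.p0 < 1.0, "p0 in (0,1)"),
            (self.fc_min > 0, "fc_min > 0"),
            (0.0 < self.fdr_max <= 1.0, "fdr_max in (0,1]"),
            (self.pseudo >= 0, "pseudo >= 0"),
            (self.flank >= 0, "flank >= 0"),
            (self.n_body_bins >= 1, "n_body_bins >= 1"),
            (self.flank_bin_bp >= 1, "flank_bin_bp >= 1"),
            (self.metagene_mode in ("subtract", "ratio"),
             "metagene_mode subtract|ratio"),
            (self.max_dist >= 0, "max_dist >= 0"),
            (self.orientation_bins >= 1, "orientation_bins >= 1"),
            (self.n_perm >= 1, "n_perm >= 1"),
            (self.overlap_strategy in ("genome", "same-chrom"),
             "overlap_strategy genome|same-chrom"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid configuration: {msg}")

    def to_dict(self) -> Dict:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    """Load a YAML mapping into a PipelineConfig; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration file must hold a key-value mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return PipelineConfig(**raw)
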