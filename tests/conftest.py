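"""Shared fixtures: a small ground-truthed study reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from gammamap.core import GenomicInterval
from gammamap.simulate import GenomeSpec, simulate_study

TINY_CHROM_SIZES = {"chr1": 1_000_000, "chr2": 1_000_000}


def jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    inter = a.intersection_length(b)
    return inter / (a.length + b.length - inter) if inter else 0.0


@pytest.fixture(scope="session")
def tiny_study():
    """A 2 x 1 Mb study with 60 genes, 200k tags and planted structure."""
    spec = GenomeSpec(chrom_sizes=TINY_CHROM_SIZES, seed=7)
    return simulate_study(spec=spec, n_genes=60, n_reads=200_000,
                          length_range=(1_000, 15_000), n_hotspot=12,
                          seed=7)


@pytest.fixture(scope="session")
def tiny_chrom_sizes():
    return dict(TINY_CHROM_SIZES)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
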