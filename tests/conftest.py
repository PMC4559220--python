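"""Shared fixtures and planting helpers for the test suite.

All fixtures are generated programmatically; nothing is read from disk
except files the tests themselves write into tmp_path.
"""

from __future__ import annotations

import numpy as np
import pytest

from abaseq import CpgIndex, Genome, HmcSite, SiteSet, SimConfig, make_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_genome():
    """100 kb single-chromosome genome at 2% CG rate."""
    cfg = SimConfig(n_chroms=1, chrom_length=100_000, cpg_rate=0.02, seed=42)
    return make_genome(cfg)


@pytest.fixture(scope="session")
def small_index(small_genome):
    return CpgIndex.from_genome(small_genome)


def plant_uniform(
    cpg_index: CpgIndex,
    rate: float,
    rng: np.random.Generator,
    individual_id: str = "planted",
    rate_fn=None,
) -> SiteSet:
    """Plant sites Bernoulli(rate) per CpG with uniform random strands.

    ``rate_fn(chrom, pos)`` overrides the flat rate per position when given.
    """
    sites = []
    for chrom in cpg_index.chroms:
        for pos in cpg_index.positions(chrom):
            p = rate_fn(chrom, int(pos)) if rate_fn else rate
            if rng.random() < p:
                strand = "+" if rng.random() < 0.5 else "-"
                sites.append(HmcSite(chrom, int(pos), strand))
    return SiteSet(individual_id, sites)


def siteset_at(positions, chrom="chr1", strand="+", individual_id="fixture") -> SiteSet:
    return SiteSet(individual_id, [HmcSite(chrom, p, strand) for p in positions])
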