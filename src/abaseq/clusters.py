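"""5hmC cluster calling, gene assignment and gene-set enrichment.

A cluster is a maximal run of at least ``min_sites`` sites (strands
pooled) in which consecutive sites are at most ``max_gap`` bp apart
(single-linkage chaining). Cluster midpoints are assigned to the
containing gene body, or otherwise to the nearest TSS within
``max_tss_distance``; more distant clusters stay unassigned and are
excluded from enrichment. Enrichment of a gene list against a flat
term-to-genes mapping uses a one-sided hypergeometric test (upper tail
when observed exceeds expected, lower otherwise) with Benjamini-Hochberg
FDR control across terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datamodel import GeneModel, HmcSite

log = logging.getLogger(__name__)

__all__ = [
    "ClusterConfig",
    "Cluster",
    "EnrichmentResult",
    "call_clusters",
    "assign_cluster_gene",
    "enrich",
]


@dataclass
class ClusterConfig:
    min_sites: int = 3
    max_gap: int = 200
    max_tss_distance: int = 250_000
    #: 'chain' joins consecutive sites <= max_gap apart; 'diameter' caps the
    #: span of a cluster at max_gap instead.
    mode: str = "chain"

    def __post_init__(self):
        if self.min_sites < 2 or self.max_gap <= 0:
            raise ValueError("need min_sites >= 2 and max_gap > 0")
        if self.mode not in ("chain", "diameter"):
            raise ValueError("mode must be 'chain' or 'diameter'")


@dataclass(frozen=True)
class Cluster:
    """A maximal run of clustered sites; end is half-open (last site + 1)."""

    chrom: str
    start: int
    end: int
    n_sites: int
    assigned_gene: Optional[str] = None
    assignment_mode: str = "unassigned"
    tss_distance: Optional[int] = None

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Cluster") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def call_clusters(
    sites: Iterable[HmcSite], cfg: Optional[ClusterConfig] = None
) -> list[Cluster]:
    """Chain strand-pooled sites into maximal clusters per chromosome."""
    cfg = cfg or ClusterConfig()
    by_chrom: dict[str, list[int]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s.pos)
    clusters: list[Cluster] = []
    for chrom in sorted(by_chrom):
        pos = by_chrom[chrom]
        if pos != sorted(pos):
            log.info("call_clusters: sorting %d sites on %s", len(pos), chrom)
            pos = sorted(pos)
        if cfg.mode == "chain":
            clusters.extend(_chain(chrom, pos, cfg))
        else:
            clusters.extend(_diameter(chrom, pos, cfg))
    return clusters


def _chain(chrom: str, pos: list[int], cfg: ClusterConfig) -> list[Cluster]:
    out = []
    run_start = 0
    for i in range(1, len(pos) + 1):
        if i == len(pos) or pos[i] - pos[i - 1] > cfg.max_gap:
            n = i - run_start
            if n >= cfg.min_sites:
                out.append(Cluster(chrom, pos[run_start], pos[i - 1] + 1, n))
            run_start = i
    return out


def _diameter(chrom: str, pos: list[int], cfg: ClusterConfig) -> list[Cluster]:
    # maximal windows whose span (last - first) stays within max_gap
    out = []
    i, n = 0, len(pos)
    while i < n:
        j = i
        while j + 1 < n and pos[j + 1] - pos[i] <= cfg.max_gap:
            j += 1
        if j - i + 1 >= cfg.min_sites:
            out.append(Cluster(chrom, pos[i], pos[j] + 1, j - i + 1))
        i = j + 1
    return out


def assign_cluster_gene(
    cluster: Cluster, genes: Sequence[GeneModel], cfg: Optional[ClusterConfig] = None
) -> Cluster:
    """Assign a cluster to the gene body containing its midpoint (smallest
    body wins when nested, then lexicographic gene_id), else to the nearest
    TSS within ``max_tss_distance``."""
    cfg = cfg or ClusterConfig()
    mid = cluster.midpoint
    containing = [
        g
        for g in genes
        if g.chrom == cluster.chrom and g.body[0] <= mid < g.body[1]
    ]
    if containing:
        best = min(containing, key=lambda g: (g.body[1] - g.body[0], g.gene_id))
        return replace(cluster, assigned_gene=best.gene_id, assignment_mode="within_body", tss_distance=abs(mid - best.tss))
    candidates = [g for g in genes if g.chrom == cluster.chrom]
    if candidates:
        best = min(candidates, key=lambda g: (abs(mid - g.tss), g.gene_id))
        dist = abs(mid - best.tss)
        if dist <= cfg.max_tss_distance:
            return replace(cluster, assigned_gene=best.gene_id, assignment_mode="nearest_tss", tss_distance=dist)
    return replace(cluster, assigned_gene=None, assignment_mode="unassigned", tss_distance=None)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    observed: int
    expected: float
    p: float
    fdr: float
    direction: str
    significant: bool


def enrich(
    gene_list: Iterable[str],
    background: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    alternative: str = "auto",
    fdr_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of ``gene_list`` against each term.

    ``alternative='auto'`` tests the upper tail when observed >= expected
    (direction 'up') and the lower tail otherwise ('down'); 'greater' and
    'less' force one tail for all terms. Benjamini-Hochberg adjustment
    runs across all terms; ``significant`` means fdr <= fdr_threshold.
    """
    if alternative not in ("auto", "greater", "less"):
        raise ValueError("alternative must be 'auto', 'greater' or 'less'")
    genes = set(gene_list)
    bg = set(background)
    missing = genes - bg
    if missing:
        raise ValueError(f"genes absent from background: {sorted(missing)[:5]}")
    M, n_list = len(bg), len(genes)

    terms = sorted(term_map)
    rows = []
    for term in terms:
        term_bg = set(term_map[term]) & bg
        observed = len(genes & term_bg)
        expected = n_list * len(term_bg) / M
        dist = hypergeom(M, len(term_bg), n_list)
        if alternative == "greater" or (alternative == "auto" and observed >= expected):
            p = float(dist.sf(observed - 1))
            direction = "up"
        else:
            p = float(dist.cdf(observed))
            direction = "down"
        rows.append((term, observed, expected, min(p, 1.0), direction))

    pvals = np.array([r[3] for r in rows])
    if pvals.size:
        _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        fdrs = np.empty(0)
    return [
        EnrichmentResult(term, obs, exp, p, float(fdr), direction, bool(fdr <= fdr_threshold))
        for (term, obs, exp, p, direction), fdr in zip(rows, fdrs)
    ]
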