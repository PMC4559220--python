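"""Multi-individual consensus, stringency tiers, hypergeometric overlap and
cohort QC summaries.

The consensus table counts, for every (chrom, pos, strand) site, how many
individuals carry it. Stringency tiers keep sites present in at least
``ceil(fraction * n_individuals)`` individuals; with the default fractions
0.25/0.50/0.75 and a 19-subject cohort this yields thresholds 5, 10 and 15.

Two-sample overlap is scored by the upper tail of a hypergeometric
distribution over a genome-wide site universe (default 27 million candidate
5hmC positions in human brain). Because realistic inputs are in the
millions, the tail is summed in log space from log-gamma terms; the
resulting log10 probability is meaningful far below linear-float underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import pearsonr

from .datamodel import HmcSite, SiteSet

__all__ = [
    "ConsensusTable",
    "StringencyConfig",
    "OverlapTest",
    "build_consensus",
    "stringency_subset",
    "hypergeom_log10_sf",
    "overlap_hypergeometric",
    "qc_summaries",
]

#: Estimated total number of 5hmC sites in the human brain genome.
DEFAULT_SITE_UNIVERSE = 27_000_000


@dataclass
class ConsensusTable:
    """Map from site key to the number of individuals carrying it."""

    entries: dict[tuple[str, int, str], int]
    n_individuals: int

    def __post_init__(self):
        for key, count in self.entries.items():
            if not 1 <= count <= self.n_individuals:
                raise ValueError(f"count {count} for {key} outside [1, {self.n_individuals}]")

    def __len__(self) -> int:
        return len(self.entries)

    def sharing_fraction(self, min_count: int) -> float:
        """Fraction of all observed sites present in at least ``min_count`` individuals."""
        if not self.entries:
            return float("nan")
        n = sum(1 for c in self.entries.values() if c >= min_count)
        return n / len(self.entries)


@dataclass
class StringencyConfig:
    """Tier fractions; threshold rule is ``min_count = ceil(fraction * n)``."""

    fractions: dict = field(
        default_factory=lambda: {"low": 0.25, "intermediate": 0.50, "high": 0.75}
    )

    def __post_init__(self):
        vals = list(self.fractions.values())
        if any(not 0 < v <= 1 for v in vals):
            raise ValueError("fractions must lie in (0, 1]")
        if vals != sorted(vals):
            raise ValueError("fractions must be ordered low < intermediate < high")

    def min_count(self, tier: str, n_individuals: int) -> int:
        if tier not in self.fractions:
            raise ValueError(f"unknown tier {tier!r}; have {sorted(self.fractions)}")
        return math.ceil(self.fractions[tier] * n_individuals)


@dataclass(frozen=True)
class OverlapTest:
    """Result of a hypergeometric two-sample overlap test."""

    N: int
    K: int
    n: int
    k: int
    log10_p: float

    @property
    def p(self) -> float:
        """Linear-space probability; underflows to 0.0 for extreme overlaps."""
        return 10.0 ** self.log10_p


def build_consensus(sitesets: Sequence[SiteSet]) -> ConsensusTable:
    """Count, per site, the number of individuals carrying it."""
    if not sitesets:
        raise ValueError("need at least one SiteSet")
    ids = [ss.individual_id for ss in sitesets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate individual_id among inputs: {sorted(ids)}")
    entries: dict[tuple[str, int, str], int] = {}
    for ss in sitesets:
        for key in ss.keys():
            entries[key] = entries.get(key, 0) + 1
    return ConsensusTable(entries, len(sitesets))


def stringency_subset(
    consensus: ConsensusTable,
    tier: Optional[str] = None,
    min_count: Optional[int] = None,
    cfg: Optional[StringencyConfig] = None,
) -> SiteSet:
    """Sites present in at least ``min_count`` individuals (or a named tier)."""
    if (tier is None) == (min_count is None):
        raise ValueError("give exactly one of tier or min_count")
    if min_count is None:
        cfg = cfg or StringencyConfig()
        min_count = cfg.min_count(tier, consensus.n_individuals)
    keys = [key for key, count in consensus.entries.items() if count >= min_count]
    name = tier if tier is not None else f"ge{min_count}"
    return SiteSet(
        f"consensus_{name}",
        (HmcSite(c, p, s, consensus.entries[(c, p, s)]) for c, p, s in keys),
    )


def _log_pmf(i: np.ndarray | int, N: int, K: int, n: int) -> np.ndarray | float:
    """log P(X = i) for X ~ Hypergeometric(N, K, n), via log-gamma."""
    i = np.asarray(i, dtype=float)
    return (
        gammaln(K + 1) - gammaln(i + 1) - gammaln(K - i + 1)
        + gammaln(N - K + 1) - gammaln(n - i + 1) - gammaln(N - K - n + i + 1)
        - gammaln(N + 1) + gammaln(n + 1) + gammaln(N - n + 1)
    )


def hypergeom_log10_sf(k: int, N: int, K: int, n: int, rel_tol: float = 1e-12) -> float:
    """log10 of P(X >= k) for X ~ Hypergeometric(N, K, n).

    Summation runs in log space term by term, starting on the thin side of
    the mode so that terms decay geometrically; it stops once the next term
    changes the running total by less than ``rel_tol`` relatively. Valid far
    below linear-float underflow.
    """
    lo = max(0, n + K - N)
    hi = min(K, n)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K, n <= N")
    if not lo <= k <= hi + 1:
        if k <= lo:
            return 0.0
        raise ValueError(f"k={k} infeasible for N={N}, K={K}, n={n}")
    if k <= lo:
        return 0.0
    if k > hi:
        return float("-inf")
    mode = (n + 1) * (K + 1) // (N + 2)
    log_tol = math.log(rel_tol)
    if k > mode:
        # upper tail directly: terms decrease for i >= k
        total = float(_log_pmf(k, N, K, n))
        lt = total
        for i in range(k + 1, hi + 1):
            lt += math.log((K - i + 1) * (n - i + 1)) - math.log(i * (N - K - n + i))
            total = np.logaddexp(total, lt)
            if lt - total < log_tol:
                break
        return total / math.log(10)
    # k at or below the mode: accumulate the lower tail P(X <= k-1) downward
    total = float(_log_pmf(k - 1, N, K, n))
    lt = total
    for i in range(k - 2, lo - 1, -1):
        # ratio pmf(i)/pmf(i+1)
        lt += math.log((i + 1) * (N - K - n + i + 1)) - math.log((K - i) * (n - i))
        total = np.logaddexp(total, lt)
        if lt - total < log_tol:
            break
    total = min(total, -1e-18)
    return math.log1p(-math.exp(total)) / math.log(10)


def overlap_hypergeometric(
    K: int, n: int, k: int, N: int = DEFAULT_SITE_UNIVERSE
) -> OverlapTest:
    """Upper-tail probability of observing >= k shared sites between a
    sample with K sites and one with n sites drawn from an N-site universe."""
    if k < 0 or k > min(K, n):
        raise ValueError(f"k={k} must satisfy 0 <= k <= min(K, n)")
    if K > N or n > N:
        raise ValueError("sample site counts cannot exceed the universe size N")
    return OverlapTest(N=N, K=K, n=n, k=k, log10_p=hypergeom_log10_sf(k, N, K, n))


def qc_summaries(
    sitesets: Sequence[SiteSet],
    metadata: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Per-individual QC table and Pearson correlations of site counts
    against read counts, age and post-mortem interval.

    ``metadata`` must have an ``individual_id`` column plus any of
    ``reads``, ``age``, ``pmi``. Correlations are reported as NaN (flagged
    undefined) with fewer than three individuals or a zero-variance
    covariate.
    """
    if "individual_id" not in metadata.columns:
        raise ValueError("metadata must have an individual_id column")
    counts = {ss.individual_id: len(ss) for ss in sitesets}
    missing = set(counts) - set(metadata["individual_id"].astype(str))
    if missing:
        raise ValueError(f"metadata missing individuals: {sorted(missing)}")
    table = metadata.copy()
    table["individual_id"] = table["individual_id"].astype(str)
    table = table[table["individual_id"].isin(counts)].reset_index(drop=True)
    table["n_sites"] = table["individual_id"].map(counts)

    stats: dict[str, dict] = {}
    for covariate in ("reads", "age", "pmi"):
        if covariate not in table.columns:
            continue
        x = table[covariate].to_numpy(dtype=float)
        y = table["n_sites"].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            stats[f"sites_vs_{covariate}"] = {"r": float("nan"), "p": float("nan"), "defined": False}
            continue
        r, p = pearsonr(x[ok], y[ok])
        stats[f"sites_vs_{covariate}"] = {"r": float(r), "p": float(p), "defined": True}
    return table, stats
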