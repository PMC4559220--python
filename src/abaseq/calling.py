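"""Single-base 5hmC site inference from aligned AbaSI reads.

AbaSI cleaves 11-13 bp downstream of a glucosylated 5hmC, so the modified
cytosine of a genuine digest read sits at read offset 11-13 from the 5'
end, on the read's own strand. The caller tests those offsets in ascending
order against the reference: the first offset showing a CpG in the read's
orientation yields a call at the plus-strand C of that CpG, and no further
offsets are tested for that read. Reads with no CpG at any tested offset
are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from .datamodel import AlignedRead, Genome, HmcSite, SiteSet

log = logging.getLogger(__name__)

__all__ = ["CallerConfig", "filter_reads", "collapse_duplicates", "call_sites"]


@dataclass
class CallerConfig:
    """Read filters and offset set for site calling.

    ``min_mean_baseq`` is a strict lower bound (a read at exactly the
    threshold is dropped); ``min_mapq`` is inclusive.
    """

    offsets: tuple[int, ...] = (11, 12, 13)
    min_mean_baseq: float = 30.0
    min_mapq: int = 10
    collapse_duplicates: bool = False
    min_support: int = 1

    def __post_init__(self):
        if not self.offsets:
            raise ValueError("offsets must be non-empty")
        if set(self.offsets) - {11, 12, 13}:
            raise ValueError("offsets must be a subset of {11, 12, 13}")
        if self.min_mean_baseq < 0 or self.min_mapq < 0 or self.min_support < 1:
            raise ValueError("thresholds must be non-negative, min_support >= 1")


def filter_reads(
    reads: Iterable[AlignedRead],
    cfg: CallerConfig,
    stats: Optional[dict] = None,
) -> Iterator[AlignedRead]:
    """Keep reads with mean_baseq strictly above and mapq at or above threshold."""
    counters = stats if stats is not None else {}
    counters.setdefault("low_baseq", 0)
    counters.setdefault("low_mapq", 0)
    counters.setdefault("kept", 0)
    for read in reads:
        if not read.mean_baseq > cfg.min_mean_baseq:
            counters["low_baseq"] += 1
            continue
        if read.mapq < cfg.min_mapq:
            counters["low_mapq"] += 1
            continue
        counters["kept"] += 1
        yield read


def collapse_duplicates(reads: Iterable[AlignedRead]) -> Iterator[AlignedRead]:
    """Keep one read per (chrom, start, strand): highest mapq, then smallest read_id.

    Input must be sorted by (chrom, start, strand); unsorted input raises.
    """
    group: list[AlignedRead] = []
    last_key = None
    for read in reads:
        key = (read.chrom, read.start, read.strand)
        if last_key is not None and key < last_key:
            raise ValueError("collapse_duplicates requires (chrom, start, strand)-sorted input")
        if group and key != last_key:
            yield min(group, key=lambda r: (-r.mapq, r.read_id))
            group = []
        group.append(read)
        last_key = key
    if group:
        yield min(group, key=lambda r: (-r.mapq, r.read_id))


def call_sites(
    reads: Iterable[AlignedRead],
    genome: Genome,
    cfg: Optional[CallerConfig] = None,
    individual_id: str = "sample",
    sex: str = "U",
) -> SiteSet:
    """Call 5hmC sites from (already filtered) reads against the reference.

    For a '+' read the candidate at offset d is reference position
    ``start + d - 1``; a call requires reference ``C,G`` at ``(c, c+1)``.
    For a '-' read the 5' end is the rightmost aligned base and offsets
    count leftward; a call requires reference ``C,G`` at ``(c-1, c)`` and
    the reported position is the plus-strand C, ``c - 1``. The first
    matching offset (ascending) wins. Support per site is the number of
    reads that called it; sites below ``min_support`` are dropped.
    """
    cfg = cfg or CallerConfig()
    offsets = sorted(cfg.offsets)
    counts: dict[tuple[str, int, str], int] = {}
    for read in reads:
        seq = genome[read.chrom]
        n = len(seq)
        hit = None
        for d in offsets:
            if read.strand == "+":
                c = read.start + d - 1
                if 0 <= c < n - 1 and seq[c] == "C" and seq[c + 1] == "G":
                    hit = (read.chrom, c, "+")
                    break
            else:
                c = read.end - 1 - (d - 1)
                if 1 <= c < n and seq[c - 1] == "C" and seq[c] == "G":
                    hit = (read.chrom, c - 1, "-")
                    break
        if hit is not None:
            counts[hit] = counts.get(hit, 0) + 1
    sites = [
        HmcSite(chrom, pos, strand, support)
        for (chrom, pos, strand), support in counts.items()
        if support >= cfg.min_support
    ]
    return SiteSet(individual_id, sites, sex)
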