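"""Core domain types and coordinate conventions.

Everything in this package is 0-based, half-open ``[start, end)``. A 5hmC
site's ``pos`` always refers to the plus-strand C of its CpG, regardless of
which strand carries the hydroxymethyl group; the ``strand`` field records
the modified strand. This makes CpG-level set operations across individuals
well defined: the same CpG hydroxymethylated on opposite strands yields two
distinct sites with identical ``pos``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "FEATURE_KINDS",
    "Genome",
    "CpgIndex",
    "HmcSite",
    "SiteSet",
    "Feature",
    "GeneModel",
    "AlignedRead",
]

#: Closed vocabulary of annotation interval kinds.
FEATURE_KINDS = frozenset(
    {
        "tss",
        "tes",
        "exon",
        "intron",
        "cpg_island",
        "cpg_shore",
        "line",
        "sine",
        "enhancer_active",
        "enhancer_poised",
        "promoter",
        "chip_peak",
    }
)

_VALID_BASES = frozenset("ACGTN")


class Genome:
    """Named uppercase DNA sequences; the coordinate frame for the pipeline.

    Parameters
    ----------
    sequences
        Mapping from chromosome name to DNA string. Lowercase input is
        uppercased; only A, C, G, T, N are accepted.
    """

    def __init__(self, sequences: Mapping[str, str]):
        seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            s = str(seq).upper()
            bad = set(s) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )
            seqs[name] = s
        self.sequences = seqs

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __len__(self) -> int:
        return len(self.sequences)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Genome({len(self)} chromosomes, {sum(self.lengths.values())} bp)"


class CpgIndex:
    """Sorted plus-strand CG dinucleotide start positions per chromosome.

    Supports half-open interval count queries, used by every density
    normalization. CpGs containing N are never indexed (an N is neither C
    nor G, so the plus-strand scan skips them naturally).
    """

    def __init__(self, positions: Mapping[str, Sequence[int]]):
        self._pos: dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.size and not np.all(np.diff(arr) > 0):
                raise ValueError(f"CpG positions for {chrom!r} not strictly increasing")
            self._pos[chrom] = arr

    @classmethod
    def from_genome(cls, genome: Genome) -> "CpgIndex":
        positions = {}
        for chrom, seq in genome.sequences.items():
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            if arr.size < 2:
                positions[chrom] = np.empty(0, dtype=np.int64)
                continue
            mask = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
            positions[chrom] = np.flatnonzero(mask).astype(np.int64)
        return cls(positions)

    @property
    def chroms(self) -> list[str]:
        return list(self._pos)

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos[chrom]

    def count(self, chrom: str, start: int, end: int) -> int:
        """Number of CG starts p with ``start <= p < end``."""
        if chrom not in self._pos:
            return 0
        arr = self._pos[chrom]
        return int(np.searchsorted(arr, end, "left") - np.searchsorted(arr, start, "left"))

    def total(self, chrom: Optional[str] = None) -> int:
        if chrom is not None:
            return int(self._pos[chrom].size)
        return int(sum(a.size for a in self._pos.values()))


@dataclass(frozen=True, order=True)
class HmcSite:
    """A strand-aware single-base 5hmC call.

    ``pos`` is the 0-based plus-strand C of the CpG; ``strand`` is the
    strand of the hydroxymethylated cytosine; ``support`` the number of
    reads backing the call.
    """

    chrom: str
    pos: int
    strand: str
    support: int = 1

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.pos < 0:
            raise ValueError("pos must be non-negative")
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)

    def check_against(self, genome: Genome) -> None:
        """Raise if the reference dinucleotide at (pos, pos+1) is not CG."""
        seq = genome[self.chrom]
        if self.pos >= len(seq) - 1:
            raise ValueError(f"{self.key}: pos beyond chromosome length {len(seq)}")
        if seq[self.pos : self.pos + 2] != "CG":
            raise ValueError(
                f"{self.key}: reference shows {seq[self.pos:self.pos + 2]!r}, expected 'CG'"
            )


class SiteSet:
    """A per-individual collection of :class:`HmcSite`, unique by (chrom, pos, strand).

    Sites are kept sorted by (chrom, pos, strand); duplicates raise.
    """

    def __init__(self, individual_id: str, sites: Iterable[HmcSite] = (), sex: str = "U"):
        if sex not in ("M", "F", "U"):
            raise ValueError(f"sex must be 'M', 'F' or 'U', got {sex!r}")
        self.individual_id = individual_id
        self.sex = sex
        ordered = sorted(sites, key=lambda s: s.key)
        for a, b in zip(ordered, ordered[1:]):
            if a.key == b.key:
                raise ValueError(f"duplicate site {a.key} in set {individual_id!r}")
        self.sites: list[HmcSite] = ordered

    @classmethod
    def from_keys(
        cls,
        keys: Iterable[tuple[str, int, str]],
        individual_id: str,
        sex: str = "U",
        support: int = 1,
    ) -> "SiteSet":
        return cls(individual_id, (HmcSite(c, p, s, support) for c, p, s in set(keys)), sex)

    def keys(self) -> set[tuple[str, int, str]]:
        return {s.key for s in self.sites}

    def merge_strands(self) -> "SiteSet":
        """Collapse symmetric CpG calls: one site per (chrom, pos), strand '+'.

        Support sums across the two strands.
        """
        agg: dict[tuple[str, int], int] = {}
        for s in self.sites:
            agg[(s.chrom, s.pos)] = agg.get((s.chrom, s.pos), 0) + s.support
        merged = [HmcSite(c, p, "+", n) for (c, p), n in agg.items()]
        return SiteSet(self.individual_id, merged, self.sex)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[HmcSite]:
        return iter(self.sites)

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        i = bisect.bisect_left(self.sites, key, key=lambda s: s.key)
        return i < len(self.sites) and self.sites[i].key == key

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"SiteSet({self.individual_id!r}, {len(self)} sites, sex={self.sex})"


@dataclass(frozen=True)
class Feature:
    """A typed annotation interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    kind: str
    strand: str = "."
    gene_id: Optional[str] = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty/inverted interval [{self.start}, {self.end})")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")

    @property
    def center(self) -> int:
        # midpoint convention: start + floor(len/2)
        return self.start + (self.end - self.start) // 2


@dataclass(frozen=True)
class GeneModel:
    """A gene with a single canonical TSS/TES and merged, sorted exons.

    For multi-transcript genes the TSS is the 5'-most transcript start on
    the plus strand and the 3'-most coordinate on the minus strand; the
    body spans the union of transcripts.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[tuple[int, int], ...]
    body: tuple[int, int]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+'/'-'")
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s0 >= e0 or s1 >= e1 or e0 > s1:
                raise ValueError(f"gene {self.gene_id}: exons must be sorted, non-overlapping")
        if self.exons and (self.exons[0][0] >= self.exons[0][1]):
            raise ValueError(f"gene {self.gene_id}: invalid exon")
        # tss upstream of tes in transcription direction
        if self.strand == "+" and self.tss > self.tes:
            raise ValueError(f"gene {self.gene_id}: tss downstream of tes on '+'")
        if self.strand == "-" and self.tss < self.tes:
            raise ValueError(f"gene {self.gene_id}: tss downstream of tes on '-'")

    @property
    def single_exon(self) -> bool:
        return len(self.exons) == 1

    @property
    def internal_exons(self) -> tuple[tuple[int, int], ...]:
        """Exons excluding the first and last in transcript order; empty for <3 exons."""
        if len(self.exons) < 3:
            return ()
        return self.exons[1:-1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]) if e0 < s1)


@dataclass(frozen=True)
class AlignedRead:
    """A single-end ungapped alignment as consumed by the site caller."""

    read_id: str
    chrom: str
    start: int
    strand: str
    length: int
    mapq: int
    mean_baseq: float

    def __post_init__(self):
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def five_prime(self) -> int:
        """Reference coordinate of the read's 5' base on its own strand."""
        return self.start if self.strand == "+" else self.end - 1
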