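"""Chromosome/feature 5hmC densities and binned signal profiles.

Density is defined as ``n_sites / (n_cg * span_bp)``: the raw site count
corrected for both the CG content and the length of the unit, so that
chromosomes or feature classes of different sizes and CpG compositions are
comparable. Profiles come in three schemes:

* ``peak``   - mean site count per contiguous 100 bp bin in a +/-3 kb
  window around ChIP-peak centers (60 bins);
* ``metagene`` - gene bodies rescaled to 50 bins with 20 kb flanks split
  into 50 fixed-width bins each (150 bins total), per expression quartile,
  orientation-flipped so bin 0 is always 5'-most;
* ``boundary`` - per-position site counts in the 20 bp flanking internal
  exons' 5' and 3' boundaries, transcript-oriented, split into sense and
  antisense strands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import CpgIndex, Feature, GeneModel, Genome, HmcSite, SiteSet

log = logging.getLogger(__name__)

__all__ = [
    "DensityRecord",
    "ProfileMatrix",
    "ExpressionTable",
    "chromosome_density",
    "feature_density",
    "peak_profile",
    "metagene_profile",
    "exon_boundary_profile",
]


@dataclass(frozen=True)
class DensityRecord:
    """5hmC density of one unit (a chromosome or a feature kind)."""

    unit: str
    n_sites: int
    n_cg: int
    span_bp: int
    density: Optional[float]

    @property
    def defined(self) -> bool:
        return self.density is not None


@dataclass
class ProfileMatrix:
    """Binned mean-signal vector for one profile scheme.

    ``coords`` holds the left edge (peak/metagene, relative bp or bin
    index) or the exact relative position (boundary) of each bin.
    """

    scheme: str
    coords: np.ndarray
    values: np.ndarray
    n_regions: int
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coord": self.coords, "value": self.values, "n": self.n_regions})


class ExpressionTable:
    """Gene expression values with rank-based quartiles (1 lowest, 4 highest).

    Quartile sizes are equal up to one gene.
    """

    def __init__(self, values: Mapping[str, float]):
        if not values:
            raise ValueError("empty expression table")
        genes = sorted(values)
        expr = np.array([values[g] for g in genes], dtype=float)
        order = np.argsort(expr, kind="stable")
        n = len(genes)
        quart = np.empty(n, dtype=int)
        quart[order] = np.arange(n) * 4 // n + 1
        self.df = pd.DataFrame({"gene_id": genes, "expression": expr, "quartile": quart})
        self._quartile = dict(zip(genes, quart))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionTable":
        return cls(dict(zip(df["gene_id"].astype(str), df["expression"].astype(float))))

    def quartile(self, gene_id: str) -> int:
        return self._quartile[gene_id]

    def genes_in_quartile(self, q: int) -> list[str]:
        return list(self.df.loc[self.df["quartile"] == q, "gene_id"])


def _positions_by_chrom(sites: Iterable[HmcSite]) -> dict[str, np.ndarray]:
    """Strand-pooled, sorted site positions per chromosome (duplicates kept:
    the same CpG hydroxymethylated on both strands counts twice)."""
    acc: dict[str, list[int]] = {}
    for s in sites:
        acc.setdefault(s.chrom, []).append(s.pos)
    return {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in acc.items()}


def _count_in(positions: dict[str, np.ndarray], chrom: str, start: int, end: int) -> int:
    arr = positions.get(chrom)
    if arr is None:
        return 0
    return int(np.searchsorted(arr, end, "left") - np.searchsorted(arr, start, "left"))


def chromosome_density(
    sites: Iterable[HmcSite], genome: Genome, cpg_index: Optional[CpgIndex] = None
) -> list[DensityRecord]:
    """One density record per chromosome: n_sites / (n_cg * chromosome length)."""
    idx = cpg_index or CpgIndex.from_genome(genome)
    positions = _positions_by_chrom(sites)
    records = []
    for chrom in genome.names:
        span = len(genome[chrom])
        n_cg = idx.total(chrom)
        n_sites = int(positions.get(chrom, np.empty(0)).size)
        if n_cg == 0 or span == 0:
            log.warning("chromosome %s has no CGs; density undefined", chrom)
            density = None
        else:
            density = n_sites / (n_cg * span)
        records.append(DensityRecord(chrom, n_sites, n_cg, span, density))
    return records


def _merge(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    merged: list[list] = []
    for chrom, s, e in sorted(intervals):
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], e)
        else:
            merged.append([chrom, s, e])
    return [tuple(iv) for iv in merged]


def feature_density(
    sites: Iterable[HmcSite], features: Sequence[Feature], cpg_index: CpgIndex
) -> list[DensityRecord]:
    """Per feature kind: density over the merged union of its intervals."""
    positions = _positions_by_chrom(sites)
    by_kind: dict[str, list[tuple[str, int, int]]] = {}
    for f in features:
        by_kind.setdefault(f.kind, []).append((f.chrom, f.start, f.end))
    records = []
    for kind in sorted(by_kind):
        merged = _merge(by_kind[kind])
        n_sites = sum(_count_in(positions, c, s, e) for c, s, e in merged)
        n_cg = sum(cpg_index.count(c, s, e) for c, s, e in merged)
        span = sum(e - s for _, s, e in merged)
        density = None if (n_cg == 0 or span == 0) else n_sites / (n_cg * span)
        if density is None:
            log.warning("feature kind %s has no CGs or zero span; density undefined", kind)
        records.append(DensityRecord(kind, n_sites, n_cg, span, density))
    return records


def peak_profile(
    sites: Iterable[HmcSite],
    peaks: Sequence[Feature],
    half_window: int = 3000,
    bin_width: int = 100,
) -> ProfileMatrix:
    """Mean site count per contiguous bin around peak centers.

    Windows extending past a chromosome edge contribute their truncated
    counts (flagged in ``meta``); the peak center of an even-length
    interval is ``start + len // 2``.
    """
    if not peaks:
        raise ValueError("no peaks supplied")
    if half_window % bin_width:
        raise ValueError("half_window must be a multiple of bin_width")
    positions = _positions_by_chrom(sites)
    nbins = 2 * half_window // bin_width
    totals = np.zeros(nbins, dtype=float)
    clipped = 0
    for peak in peaks:
        center = peak.center
        lo = center - half_window
        if lo < 0:
            clipped += 1
        arr = positions.get(peak.chrom)
        if arr is None:
            continue
        sel = arr[(arr >= lo) & (arr < center + half_window)]
        if sel.size:
            np.add.at(totals, (sel - lo) // bin_width, 1.0)
    if clipped:
        log.info("%d peak windows truncated at a chromosome edge", clipped)
    coords = np.arange(-half_window, half_window, bin_width)
    return ProfileMatrix(
        "peak", coords, totals / len(peaks), len(peaks), {"clipped_windows": clipped}
    )


def _gene_bin_edges(gene: GeneModel, flank: int, nbins: int) -> np.ndarray:
    """151 absolute edges, plus-orientation: flank | body | flank, 50 bins each."""
    start, end = gene.body
    up = np.linspace(start - flank, start, nbins + 1)[:-1]
    body = np.linspace(start, end, nbins + 1)[:-1]
    down = np.linspace(end, end + flank, nbins + 1)
    return np.concatenate([up, body, down])


def metagene_profile(
    sites: Iterable[HmcSite],
    genes: Sequence[GeneModel],
    expression: ExpressionTable,
    flank: int = 20_000,
    nbins: int = 50,
    per_cpg: bool = False,
    cpg_index: Optional[CpgIndex] = None,
) -> dict[int, ProfileMatrix]:
    """Per expression quartile: 150-bin metagene profile (flank|body|flank).

    Per-gene bin values are site counts divided by bin width in bp (or by
    bin CG count when ``per_cpg``); quartile values average per-gene
    vectors so every gene weighs equally. Genes with a body shorter than
    ``nbins`` bp are skipped with a logged count; bins reaching past a
    chromosome start simply collect no sites.
    """
    if per_cpg and cpg_index is None:
        raise ValueError("per_cpg normalization requires a CpgIndex")
    positions = _positions_by_chrom(sites)
    sums: dict[int, np.ndarray] = {q: np.zeros(3 * nbins) for q in (1, 2, 3, 4)}
    counts = {q: 0 for q in (1, 2, 3, 4)}
    skipped = 0
    for gene in genes:
        try:
            q = expression.quartile(gene.gene_id)
        except KeyError:
            continue
        if gene.body[1] - gene.body[0] < nbins:
            skipped += 1
            continue
        edges = _gene_bin_edges(gene, flank, nbins)
        arr = positions.get(gene.chrom, np.empty(0, dtype=np.int64))
        sel = arr[(arr >= edges[0]) & (arr < edges[-1])]
        binned = np.searchsorted(edges, sel, "right") - 1
        counts_vec = np.bincount(binned, minlength=3 * nbins).astype(float)[: 3 * nbins]
        if per_cpg:
            norm = np.array(
                [
                    max(cpg_index.count(gene.chrom, int(np.ceil(a)), int(np.ceil(b))), 0)
                    for a, b in zip(edges[:-1], edges[1:])
                ],
                dtype=float,
            )
            norm[norm == 0] = np.nan
        else:
            norm = np.diff(edges)
        vec = counts_vec / norm
        if gene.strand == "-":
            vec = vec[::-1]
        sums[q] += np.nan_to_num(vec)
        counts[q] += 1
    if skipped:
        log.info("metagene: skipped %d genes with body < %d bp", skipped, nbins)
    out = {}
    for q in (1, 2, 3, 4):
        values = sums[q] / counts[q] if counts[q] else np.full(3 * nbins, np.nan)
        out[q] = ProfileMatrix(
            "metagene",
            np.arange(3 * nbins),
            values,
            counts[q],
            {"flank": flank, "nbins": nbins, "per_cpg": per_cpg},
        )
    return out


def exon_boundary_profile(
    sites: Iterable[HmcSite],
    genes: Sequence[GeneModel],
    flank: int = 20,
) -> tuple[ProfileMatrix, ProfileMatrix]:
    """Per-position site counts around internal exon boundaries.

    First and last exons and single-exon genes are excluded. Positions are
    transcript-oriented: for the 5' boundary, 0 is the first exonic base
    and -1 the last intronic base upstream; for the 3' boundary, 0 is the
    first intronic base downstream and -1 the last exonic base. The profile
    concatenates [5' boundary -flank..flank-1 | 3' boundary -flank..flank-1].
    The sense matrix counts sites on the gene's strand, antisense the
    opposite.
    """
    pos_by_strand: dict[tuple[str, str], np.ndarray] = {}
    acc: dict[tuple[str, str], list[int]] = {}
    for s in sites:
        acc.setdefault((s.chrom, s.strand), []).append(s.pos)
    for key, p in acc.items():
        pos_by_strand[key] = np.sort(np.asarray(p, dtype=np.int64))

    width = 2 * flank
    sense = np.zeros(2 * width)
    antisense = np.zeros(2 * width)
    n_exons = 0

    def add(profile: np.ndarray, arr: np.ndarray, lo: int, hi: int, rel_fn, base: int):
        sel = arr[(arr >= lo) & (arr < hi)]
        for g in sel:
            rel = rel_fn(int(g))
            if -flank <= rel < flank:
                profile[base + rel + flank] += 1

    for gene in genes:
        internal = gene.internal_exons
        if not internal:
            continue
        for s, e in internal:
            n_exons += 1
            if gene.strand == "+":
                bounds = [(s, lambda g, s=s: g - s, 0), (e, lambda g, e=e: g - e, width)]
            else:
                bounds = [(e, lambda g, e=e: e - 1 - g, 0), (s, lambda g, s=s: s - 1 - g, width)]
            for _, rel_fn, base in bounds:
                for strand_sites, profile in (
                    (gene.strand, sense),
                    ("-" if gene.strand == "+" else "+", antisense),
                ):
                    arr = pos_by_strand.get((gene.chrom, strand_sites))
                    if arr is None:
                        continue
                    lo, hi = min(s, e) - flank - 1, max(s, e) + flank + 1
                    add(profile, arr, lo, hi, rel_fn, base)

    coords = np.concatenate([np.arange(-flank, flank), np.arange(-flank, flank)])
    meta = {"flank": flank, "blocks": ["five_prime", "three_prime"]}
    return (
        ProfileMatrix("boundary", coords, sense, n_exons, dict(meta, strand="sense")),
        ProfileMatrix("boundary", coords, antisense, n_exons, dict(meta, strand="antisense")),
    )
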