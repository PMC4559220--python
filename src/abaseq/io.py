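"""Readers and writers for the external formats the pipeline touches.

FASTA genomes, SAM/BAM alignments, BED6 site files, BED-like annotation
files, a gene-model TSV and plain TSV tables for expression and
X-inactivation escape scores. All on-disk interval formats are BED-style
0-based half-open; round-tripping a :class:`~abaseq.datamodel.SiteSet`
through BED6 is the identity.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import pandas as pd
import pysam
from Bio import SeqIO

from .datamodel import (
    AlignedRead,
    Feature,
    FEATURE_KINDS,
    GeneModel,
    Genome,
    SiteSet,
    HmcSite,
)

log = logging.getLogger(__name__)

__all__ = [
    "load_genome",
    "write_genome",
    "read_alignments",
    "write_sites",
    "read_sites",
    "load_annotations",
    "write_features",
    "write_gene_models",
    "read_expression",
    "read_escape",
]


def load_genome(path: str | Path) -> Genome:
    """Load a FASTA file into a :class:`Genome` (uppercased, order preserved)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as handle:
        first = handle.readline()
        if first and not first.startswith(">"):
            raise ValueError(f"{path}: line 1: expected FASTA header starting with '>'")
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate sequence name {rec.id!r}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return Genome(records)


def write_genome(genome: Genome, path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as out:
        for name, seq in genome.sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
    return path


def read_alignments(
    path: str | Path,
    genome: Optional[Genome] = None,
    stats: Optional[dict] = None,
) -> Iterator[AlignedRead]:
    """Stream mapped reads from a SAM/BAM file as :class:`AlignedRead`.

    Unmapped records are skipped; strand comes from the reverse flag;
    ``mean_baseq`` is the arithmetic mean of the base qualities. Reads whose
    CIGAR is not a single full-length match are skipped with a logged count
    (the pipeline assumes ungapped alignments). If *genome* is given, a
    record on an unknown chromosome raises.
    """
    counters = stats if stats is not None else {}
    counters.setdefault("unmapped", 0)
    counters.setdefault("nontrivial_cigar", 0)
    counters.setdefault("kept", 0)
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped:
                counters["unmapped"] += 1
                continue
            chrom = rec.reference_name
            if genome is not None and chrom not in genome:
                raise ValueError(f"{path}: read on chromosome {chrom!r} absent from genome")
            cig = rec.cigartuples
            if cig is not None and (len(cig) != 1 or cig[0][0] != 0):
                counters["nontrivial_cigar"] += 1
                continue
            quals = rec.query_qualities
            mean_q = float(sum(quals)) / len(quals) if quals else 0.0
            counters["kept"] += 1
            yield AlignedRead(
                read_id=rec.query_name,
                chrom=chrom,
                start=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                length=rec.query_length or rec.reference_length or 0,
                mapq=rec.mapping_quality,
                mean_baseq=mean_q,
            )
    if counters["nontrivial_cigar"]:
        log.info("%s: skipped %d reads with non-trivial CIGAR", path, counters["nontrivial_cigar"])


def write_sites(path: str | Path, sites: SiteSet) -> Path:
    """Write a site set as BED6: chrom, pos, pos+1, individual_id, support, strand."""
    path = Path(path)
    with open(path, "w") as out:
        for s in sites:
            out.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{sites.individual_id}\t{s.support}\t{s.strand}\n")
    return path


def read_sites(path: str | Path, sex: str = "U") -> SiteSet:
    """Read a BED6 site file written by :func:`write_sites` (lossless round-trip)."""
    path = Path(path)
    sites = []
    individual_id = path.stem
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 BED fields, got {len(fields)}")
            try:
                chrom, start, end, name, support, strand = fields
                pos = int(start)
                if int(end) != pos + 1:
                    raise ValueError("end != start + 1")
                sites.append(HmcSite(chrom, pos, strand, int(support)))
                individual_id = name
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return SiteSet(individual_id, sites, sex)


def _parse_bed_intervals(path: str | Path) -> list[tuple[str, int, int, str, Optional[str]]]:
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else "."
            rows.append((chrom, start, end, strand, name))
    return rows


def _clip(chrom: str, start: int, end: int, genome: Optional[Genome]) -> Optional[tuple[int, int]]:
    if genome is None:
        return (start, end) if start < end else None
    if chrom not in genome:
        raise ValueError(f"interval on chromosome {chrom!r} absent from genome")
    length = len(genome[chrom])
    s, e = max(0, start), min(end, length)
    if (s, e) != (start, end):
        log.warning("clipped interval %s:[%d,%d) to [%d,%d)", chrom, start, end, s, e)
    return (s, e) if s < e else None


def load_annotations(
    feature_paths: Mapping[str, str | Path],
    gene_path: Optional[str | Path] = None,
    genome: Optional[Genome] = None,
    shore_width: int = 2000,
) -> tuple[list[Feature], list[GeneModel]]:
    """Load typed BED annotation files and an optional gene-model TSV.

    CpG shores are auto-derived as the ``shore_width`` flanks of each CpG
    island, clipped to chromosome bounds and excluding the island itself.
    Output ordering is deterministic (sorted), independent of input order.
    """
    features: list[Feature] = []
    for kind, path in feature_paths.items():
        if kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {kind!r}")
        for chrom, start, end, strand, name in _parse_bed_intervals(path):
            clipped = _clip(chrom, start, end, genome)
            if clipped is None:
                continue
            features.append(Feature(chrom, clipped[0], clipped[1], kind, strand, name))

    # shores: 2 kb flanks of islands, excluding the island itself
    for island in [f for f in features if f.kind == "cpg_island"]:
        for s, e in ((island.start - shore_width, island.start), (island.end, island.end + shore_width)):
            clipped = _clip(island.chrom, s, e, genome)
            if clipped is not None and clipped[0] < clipped[1]:
                features.append(Feature(island.chrom, clipped[0], clipped[1], "cpg_shore"))

    genes: list[GeneModel] = []
    if gene_path is not None:
        genes = _load_gene_models(gene_path)

    features.sort(key=lambda f: (f.kind, f.chrom, f.start, f.end))
    genes.sort(key=lambda g: g.gene_id)
    return features, genes


def _load_gene_models(path: str | Path) -> list[GeneModel]:
    """Gene TSV: chrom, start, end, gene_id, strand, exon_starts, exon_ends.

    Multiple rows with the same gene_id are treated as transcripts: the
    canonical TSS is the 5'-most transcript start on '+' and the 3'-most
    coordinate on '-'; exons are merged across transcripts.
    """
    per_gene: dict[str, list] = defaultdict(list)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}: line {lineno}: expected 7 gene fields")
            chrom, start, end, gene_id, strand = fields[0], int(fields[1]), int(fields[2]), fields[3], fields[4]
            ex_starts = [int(x) for x in fields[5].split(",") if x]
            ex_ends = [int(x) for x in fields[6].split(",") if x]
            if len(ex_starts) != len(ex_ends):
                raise ValueError(f"{path}: line {lineno}: exon start/end count mismatch")
            per_gene[gene_id].append((chrom, start, end, strand, list(zip(ex_starts, ex_ends))))

    genes = []
    for gene_id, transcripts in per_gene.items():
        chrom = transcripts[0][0]
        strand = transcripts[0][3]
        body = (min(t[1] for t in transcripts), max(t[2] for t in transcripts))
        if strand == "+":
            tss, tes = body[0], body[1] - 1
        else:
            tss, tes = body[1] - 1, body[0]
        exons = _merge_intervals([ex for t in transcripts for ex in t[4]])
        genes.append(GeneModel(gene_id, chrom, strand, tss, tes, tuple(exons), body))
    return genes


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


def write_features(features: Iterable[Feature], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as out:
        for f in features:
            name = f.gene_id or "."
            out.write(f"{f.chrom}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n")
    return path


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as out:
        out.write("#chrom\tstart\tend\tgene_id\tstrand\texon_starts\texon_ends\n")
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons)
            ends = ",".join(str(e) for _, e in g.exons)
            out.write(f"{g.chrom}\t{g.body[0]}\t{g.body[1]}\t{g.gene_id}\t{g.strand}\t{starts}\t{ends}\n")
    return path


def read_expression(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene_id, expression."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "expression"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns gene_id, expression")
    return df


def read_escape(path: str | Path) -> dict[str, int]:
    """TSV with columns gene_id, score (integers 0-9)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "score"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns gene_id, score")
    scores = {}
    for gene_id, score in zip(df["gene_id"], df["score"]):
        score = int(score)
        if not 0 <= score <= 9:
            raise ValueError(f"{path}: escape score {score} for {gene_id} outside 0-9")
        scores[str(gene_id)] = score
    return scores
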