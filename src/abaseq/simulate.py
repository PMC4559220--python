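"""Synthetic genomes, multi-individual 5hmC truth sets, AbaSI-style reads
and annotation fixtures.

The simulator emulates the geometry of an AbaSI digest library: the enzyme
cleaves 11-13 bp downstream of a glucosylated 5hmC, so the 5' end of a
sequencing read sits such that the hydroxymethylated C occupies read offset
11-13 (1-based, counted along the read's own strand). Reads are emitted
pre-aligned (SAM); alignment itself is outside this package's scope.

Cohort structure follows a shared-core-plus-private-sites model: a core set
of hydroxymethylated CpGs common to every individual, plus per-individual
private sites drawn independently, which reproduces the monotone sharing
spectrum seen across unrelated brains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .datamodel import CpgIndex, Feature, GeneModel, Genome, HmcSite, SiteSet

log = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "TruthTable",
    "make_genome",
    "plant_truth",
    "simulate_reads",
    "write_fastq",
    "make_annotations",
]


@dataclass
class SimConfig:
    """Parameters of a synthetic cohort.

    ``offset_weights`` gives the probability of the hydroxymethylated C
    landing at read offset 11, 12 or 13; the default puts half the mass on
    12 with symmetric shoulders. ``noise_read_rate`` is background reads per
    kb of genome, uniform in position and strand, approximating the library
    fraction that carries no informative CpG at the expected offset.
    """

    n_chroms: int = 2
    chrom_length: int = 100_000
    cpg_rate: float = 0.02
    n_individuals: int = 19
    core_fraction: float = 0.2
    private_rate: float = 0.02
    reads_per_site: float = 5.0
    offset_weights: dict = field(default_factory=lambda: {11: 0.25, 12: 0.5, 13: 0.25})
    noise_read_rate: float = 1.0
    read_length: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_chroms < 1 or self.chrom_length < 1000:
            raise ValueError("need n_chroms >= 1 and chrom_length >= 1000")
        if not 0 <= self.cpg_rate <= 0.5:
            raise ValueError("cpg_rate must be in [0, 0.5]")
        if self.cpg_rate > 0.25:
            raise ValueError("cpg_rate > 0.25 cannot be placed with CpG spacing >= 3 bp")
        for name in ("core_fraction", "private_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if set(self.offset_weights) - {11, 12, 13}:
            raise ValueError("offset_weights keys must be within {11, 12, 13}")
        total = sum(self.offset_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"offset_weights must sum to 1, got {total}")
        if self.reads_per_site <= 0 or self.read_length < 14:
            raise ValueError("reads_per_site must be > 0 and read_length >= 14")

    @property
    def chrom_names(self) -> list[str]:
        """``chr1..chrN``; with >= 2 chromosomes the last one is ``chrX``."""
        names = [f"chr{i + 1}" for i in range(self.n_chroms)]
        if self.n_chroms >= 2:
            names[-1] = "chrX"
        return names


@dataclass
class TruthTable:
    """Planted per-individual site sets plus the shared core set."""

    individuals: list[SiteSet]
    core: SiteSet

    def __post_init__(self):
        core_keys = self.core.keys()
        for ss in self.individuals:
            if not core_keys <= ss.keys():
                raise ValueError(f"core set not contained in individual {ss.individual_id!r}")

    def sharing_counts(self) -> dict[tuple[str, int, str], int]:
        counts: dict[tuple[str, int, str], int] = {}
        for ss in self.individuals:
            for key in ss.keys():
                counts[key] = counts.get(key, 0) + 1
        return counts


_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _make_chromosome(n: int, cpg_rate: float, rng: np.random.Generator) -> str:
    """I.i.d. background bases with all chance CGs removed, then exactly
    ``round(cpg_rate * n)`` CG dinucleotides injected with pairwise start
    spacing >= 3 bp.

    The spacing guarantee means a read carrying a planted CpG at offset d
    can never show a different CpG at a smaller tested offset, so offset
    resolution in the caller is exact on noise-free data.
    """
    b = rng.integers(0, 4, size=n, dtype=np.int8)  # 0=A 1=C 2=G 3=T
    # kill chance CG dinucleotides by rewriting the C to A/T (cannot create new CG)
    cg = np.flatnonzero((b[:-1] == 1) & (b[1:] == 2))
    if cg.size:
        b[cg] = rng.choice(np.array([0, 3], dtype=np.int8), size=cg.size)
    m = int(round(cpg_rate * n))
    if m > 0:
        occupied = np.zeros(n, dtype=bool)
        placed = 0
        for p in rng.permutation(n - 1):
            if occupied[max(0, p - 2) : p + 3].any():
                continue
            b[p], b[p + 1] = 1, 2
            occupied[max(0, p - 2) : min(n, p + 3)] = True
            placed += 1
            if placed == m:
                break
        else:
            raise ValueError(f"could not place {m} CpGs with spacing >= 3 in {n} bp")
    return _BASE_LUT[b].tobytes().decode("ascii")


def make_genome(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> Genome:
    """Generate a synthetic genome with a controlled CG dinucleotide rate."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    return Genome({name: _make_chromosome(cfg.chrom_length, cfg.cpg_rate, rng) for name in cfg.chrom_names})


def plant_truth(
    genome: Genome,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    cpg_index: Optional[CpgIndex] = None,
) -> TruthTable:
    """Plant per-individual true site sets over the genome's CpGs.

    A core fraction of the eligible CpG pool is hydroxymethylated in every
    individual (with a fixed strand per core site); each individual then
    adds private sites independently at ``private_rate`` per remaining CpG,
    with uniformly assigned strands. CpGs closer than one read length to a
    chromosome edge are excluded so that every planted site is sequencable.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    idx = cpg_index or CpgIndex.from_genome(genome)
    pool: list[tuple[str, int]] = []
    for chrom in genome.names:
        length = len(genome[chrom])
        pos = idx.positions(chrom)
        ok = pos[(pos >= cfg.read_length) & (pos <= length - cfg.read_length - 1)]
        pool.extend((chrom, int(p)) for p in ok)
    if not pool:
        raise ValueError("genome has no eligible CpG positions to plant sites on")

    perm = rng.permutation(len(pool))
    core_n = int(round(cfg.core_fraction * len(pool)))
    core_idx = perm[:core_n]
    rest_idx = perm[core_n:]
    strands = np.array(["+", "-"])
    core_strands = rng.choice(strands, size=core_n)
    core_sites = [
        HmcSite(pool[i][0], pool[i][1], s) for i, s in zip(core_idx, core_strands)
    ]
    core = SiteSet("core", core_sites)

    individuals = []
    for k in range(cfg.n_individuals):
        take = rng.random(len(rest_idx)) < cfg.private_rate
        priv_strands = rng.choice(strands, size=int(take.sum()))
        private = [
            HmcSite(pool[i][0], pool[i][1], s)
            for i, s in zip(rest_idx[take], priv_strands)
        ]
        individuals.append(SiteSet(f"ind{k + 1:02d}", core_sites + private))
    return TruthTable(individuals, core)


def _read_start(pos: int, strand: str, offset: int, read_length: int) -> int:
    """Leftmost aligned position of a read whose 5' end places the site's
    hydroxymethylated C at 1-based read offset ``offset``.

    '+' strand: the C is the plus-strand C at ``pos``. '-' strand: the C is
    the minus-strand base at plus-coordinate ``pos + 1``, counted from the
    read's 5' end, i.e. its rightmost aligned base.
    """
    if strand == "+":
        return pos - (offset - 1)
    return pos + offset - read_length + 1


def simulate_reads(
    genome: Genome,
    siteset: SiteSet,
    cfg: SimConfig,
    path: str | Path,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Write AbaSI-style aligned reads for one individual to a SAM file.

    Each site receives a zero-truncated Poisson number of reads (mean
    ``reads_per_site``; truncation at one read guarantees every planted
    site is observable). Signal reads have MAPQ 42 and uniformly high base
    qualities; background reads are uniform in position and strand with
    mixed MAPQ. Returns counters for signal/noise/skipped reads.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    offsets = np.array(sorted(cfg.offset_weights), dtype=int)
    probs = np.array([cfg.offset_weights[int(d)] for d in offsets], dtype=float)
    probs = probs / probs.sum()
    L = cfg.read_length
    qual = pysam.qualitystring_to_array("I" * L)

    records: list[tuple[str, int, int, int, str, str]] = []  # chrom, start, flag, mapq, read_id, seq
    n_skipped = 0
    for i, site in enumerate(siteset):
        seq = genome[site.chrom]
        n_reads = max(1, int(rng.poisson(cfg.reads_per_site)))
        ds = offsets[rng.choice(len(offsets), size=n_reads, p=probs)]
        for j, d in enumerate(ds):
            start = _read_start(site.pos, site.strand, int(d), L)
            if start < 0 or start + L > len(seq):
                n_skipped += 1
                continue
            flag = 0 if site.strand == "+" else 16
            records.append((site.chrom, start, flag, 42, f"sig{i}_{j}", seq[start : start + L]))
    if n_skipped:
        log.info("%s: skipped %d reads too close to a chromosome edge", siteset.individual_id, n_skipped)

    n_noise = 0
    for chrom in genome.names:
        seq = genome[chrom]
        if len(seq) < L:
            continue
        count = int(rng.poisson(cfg.noise_read_rate * len(seq) / 1000.0))
        if count == 0:
            continue
        starts = rng.integers(0, len(seq) - L + 1, size=count)
        flags = rng.choice(np.array([0, 16]), size=count)
        mapqs = rng.integers(0, 43, size=count)
        for j in range(count):
            records.append((chrom, int(starts[j]), int(flags[j]), int(mapqs[j]), f"noise_{chrom}_{j}", seq[starts[j] : starts[j] + L]))
        n_noise += count

    order = {name: i for i, name in enumerate(genome.names)}
    records.sort(key=lambda r: (order[r[0]], r[1], r[2], r[4]))

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": genome.lengths[name]} for name in genome.names],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for chrom, start, flag, mapq, read_id, seq in records:
            a = pysam.AlignedSegment(header)
            a.query_name = read_id
            a.flag = flag
            a.reference_id = order[chrom]
            a.reference_start = start
            a.mapping_quality = mapq
            a.cigartuples = [(0, L)]
            a.query_sequence = seq
            a.query_qualities = qual
            out.write(a)
    return {"signal": len(records) - n_noise, "noise": n_noise, "skipped": n_skipped}


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def write_fastq(sam_path: str | Path, fastq_path: str | Path) -> Path:
    """Dump simulated reads to FASTQ in sequencing orientation.

    Provided for completeness; the pipeline itself consumes aligned reads.
    """
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as af, open(fastq_path, "w") as out:
        for rec in af:
            seq = rec.query_sequence or ""
            qual = "".join(chr(q + 33) for q in (rec.query_qualities or []))
            if rec.is_reverse:
                seq = seq.translate(_COMPLEMENT)[::-1]
                qual = qual[::-1]
            out.write(f"@{rec.query_name}\n{seq}\n+\n{qual}\n")
    return Path(fastq_path)


def make_annotations(
    genome: Genome,
    rng: Optional[np.random.Generator] = None,
    *,
    seed: int = 0,
    genes_per_chrom: int = 10,
    exons_per_gene: int = 4,
    exon_length: int = 300,
    intron_length: int = 500,
    gene_gap: int = 1500,
    start_margin: int = 2000,
    islands_per_chrom: int = 3,
    island_length: int = 500,
    intergenic_feature_length: int = 400,
    expression_sigma: float = 1.0,
    x_chrom: str = "chrX",
) -> tuple[list[Feature], list[GeneModel], pd.DataFrame, pd.DataFrame]:
    """Build annotation fixtures over a synthetic genome.

    Non-overlapping multi-exon genes are tiled with gaps on alternating
    strands; CpG islands are placed over the most CG-dense windows;
    enhancer and ChIP-peak intervals go into intergenic gaps. Expression is
    log-normal per gene; genes on ``x_chrom`` (if present) receive
    X-inactivation escape scores cycling over 0-9.

    Returns ``(features, gene_models, expression_df, escape_df)``.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    idx = CpgIndex.from_genome(genome)
    gene_len = exons_per_gene * exon_length + (exons_per_gene - 1) * intron_length

    genes: list[GeneModel] = []
    features: list[Feature] = []
    for chrom in genome.names:
        length = len(genome[chrom])
        needed = start_margin * 2 + genes_per_chrom * (gene_len + gene_gap)
        if needed > length:
            raise ValueError(
                f"{chrom}: cannot place {genes_per_chrom} genes of {gene_len} bp in {length} bp"
            )
        pos = start_margin
        gene_regions = []
        for g in range(genes_per_chrom):
            strand = "+" if g % 2 == 0 else "-"
            exons = tuple(
                (pos + k * (exon_length + intron_length), pos + k * (exon_length + intron_length) + exon_length)
                for k in range(exons_per_gene)
            )
            body = (exons[0][0], exons[-1][1])
            tss, tes = (body[0], body[1] - 1) if strand == "+" else (body[1] - 1, body[0])
            gene_id = f"{chrom}_g{g:03d}"
            genes.append(GeneModel(gene_id, chrom, strand, tss, tes, exons, body))
            gene_regions.append(body)
            for s, e in exons:
                features.append(Feature(chrom, s, e, "exon", strand, gene_id))
            for s, e in zip([e for _, e in exons[:-1]], [s for s, _ in exons[1:]]):
                features.append(Feature(chrom, s, e, "intron", strand, gene_id))
            features.append(Feature(chrom, max(0, tss - 250), min(length, tss + 250), "tss", strand, gene_id))
            features.append(Feature(chrom, max(0, tes - 250), min(length, tes + 250), "tes", strand, gene_id))
            pos += gene_len + gene_gap

        # CpG islands over the most CG-dense non-overlapping windows
        starts = np.arange(0, length - island_length, island_length)
        cg_counts = np.array([idx.count(chrom, int(s), int(s + island_length)) for s in starts])
        top = starts[np.argsort(cg_counts, kind="stable")[::-1][:islands_per_chrom]]
        for s in sorted(int(x) for x in top):
            features.append(Feature(chrom, s, s + island_length, "cpg_island"))

        # intergenic enhancers / ChIP peaks in the gaps between gene bodies
        kinds = ["enhancer_active", "enhancer_poised", "chip_peak"]
        for i, (body, nxt) in enumerate(zip(gene_regions, gene_regions[1:])):
            gap_start, gap_end = body[1], nxt[0]
            if gap_end - gap_start < intergenic_feature_length + 100:
                continue
            s = gap_start + (gap_end - gap_start - intergenic_feature_length) // 2
            features.append(Feature(chrom, s, s + intergenic_feature_length, kinds[i % len(kinds)]))

    expr = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "expression": np.exp(rng.normal(0.0, expression_sigma, size=len(genes))),
        }
    )
    x_genes = [g.gene_id for g in genes if g.chrom == x_chrom]
    scores = np.arange(len(x_genes)) % 10
    rng.shuffle(scores)
    escape = pd.DataFrame({"gene_id": x_genes, "score": scores.astype(int)})
    features.sort(key=lambda f: (f.kind, f.chrom, f.start, f.end))
    return features, genes, expr, escape
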