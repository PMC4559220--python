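"""Synthetic cohort generator: genome composition, truth planting,
read geometry and determinism."""

import numpy as np
import pytest

from abaseq import (
    CpgIndex,
    SimConfig,
    make_annotations,
    make_genome,
    plant_truth,
    simulate_reads,
)
from abaseq import io as aio


class TestMakeGenome:
    def test_deterministic(self):
        cfg = SimConfig(n_chroms=1, chrom_length=10_000, seed=7)
        assert make_genome(cfg).sequences == make_genome(cfg).sequences

    def test_cpg_rate_zero_leaves_no_cg(self):
        cfg = SimConfig(n_chroms=1, chrom_length=100_000, cpg_rate=0.0, seed=1)
        idx = CpgIndex.from_genome(make_genome(cfg))
        assert idx.total() / 100_000 < 0.01

    def test_cpg_rate_realized(self):
        cfg = SimConfig(n_chroms=1, chrom_length=100_000, cpg_rate=0.02, seed=2)
        idx = CpgIndex.from_genome(make_genome(cfg))
        assert 1600 <= idx.total() <= 2400

    def test_excessive_rate_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(cpg_rate=0.6)

    def test_chrx_is_last_chromosome(self):
        cfg = SimConfig(n_chroms=3, chrom_length=10_000)
        assert cfg.chrom_names == ["chr1", "chr2", "chrX"]


class TestPlantTruth:
    def test_degenerate_all_identical(self):
        cfg = SimConfig(n_chroms=1, chrom_length=50_000, core_fraction=1.0, private_rate=0.0, n_individuals=4, seed=3)
        truth = plant_truth(make_genome(cfg), cfg)
        keys = truth.individuals[0].keys()
        assert all(ss.keys() == keys for ss in truth.individuals)
        assert truth.core.keys() == keys

    def test_private_overlap_matches_binomial_expectation(self):
        cfg = SimConfig(
            n_chroms=1, chrom_length=500_000, cpg_rate=0.02,
            core_fraction=0.0, private_rate=0.1, n_individuals=2, seed=4,
        )
        genome = make_genome(cfg)
        truth = plant_truth(genome, cfg)
        n_pool = len(
            [p for p in CpgIndex.from_genome(genome).positions("chr1")
             if cfg.read_length <= p <= cfg.chrom_length - cfg.read_length - 1]
        )
        # each individual picks a (position, strand); overlap needs same position AND strand
        expected = n_pool * cfg.private_rate**2 * 0.5
        sigma = np.sqrt(expected)
        observed = len(truth.individuals[0].keys() & truth.individuals[1].keys())
        assert abs(observed - expected) <= 3 * sigma + 1

    def test_sharing_spans_full_range_and_is_monotone(self):
        cfg = SimConfig(n_chroms=1, chrom_length=100_000, core_fraction=0.1, private_rate=0.2, n_individuals=19, seed=5)
        truth = plant_truth(make_genome(cfg), cfg)
        counts = list(truth.sharing_counts().values())
        assert min(counts) == 1 and max(counts) == 19
        total = len(counts)
        fractions = [sum(1 for c in counts if c >= k) / total for k in range(1, 20)]
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))


class TestSimulateReads:
    def test_plus_strand_offset_geometry(self, tmp_path):
        # one '+' site, offset 11 only: read start = pos - 10, CG at read offsets 11-12
        seq = "A" * 100 + "CG" + "A" * 100
        from abaseq import Genome, HmcSite, SiteSet

        genome = Genome({"chr1": seq})
        cfg = SimConfig(
            n_chroms=1, chrom_length=1000, offset_weights={11: 1.0},
            reads_per_site=1.0, noise_read_rate=0.0, seed=6,
        )
        ss = SiteSet("x", [HmcSite("chr1", 100, "+")])
        simulate_reads(genome, ss, cfg, tmp_path / "r.sam")
        reads = list(aio.read_alignments(tmp_path / "r.sam", genome))
        assert all(r.start == 90 and r.strand == "+" for r in reads)
        assert all(seq[r.start + 10 : r.start + 12] == "CG" for r in reads)

    def test_minus_strand_mirrored_geometry(self, tmp_path):
        from abaseq import Genome, HmcSite, SiteSet

        seq = "A" * 100 + "CG" + "A" * 100
        genome = Genome({"chr1": seq})
        cfg = SimConfig(
            n_chroms=1, chrom_length=1000, offset_weights={11: 1.0},
            reads_per_site=1.0, noise_read_rate=0.0, read_length=50, seed=6,
        )
        ss = SiteSet("x", [HmcSite("chr1", 100, "-")])
        simulate_reads(genome, ss, cfg, tmp_path / "r.sam")
        reads = list(aio.read_alignments(tmp_path / "r.sam", genome))
        # 5' end of a '-' read is its rightmost base; offset 11 lands on pos+1
        assert all(r.strand == "-" and r.end - 1 - 10 == 101 for r in reads)

    def test_total_reads_poisson_bound(self, tmp_path, small_genome):
        cfg = SimConfig(n_chroms=1, chrom_length=100_000, reads_per_site=5.0, noise_read_rate=0.0, seed=7)
        idx = CpgIndex.from_genome(small_genome)
        from abaseq import HmcSite, SiteSet

        positions = idx.positions("chr1")
        positions = positions[(positions >= 50) & (positions < 99_900)][:100]
        ss = SiteSet("x", [HmcSite("chr1", int(p), "+") for p in positions])
        stats = simulate_reads(small_genome, ss, cfg, tmp_path / "r.sam")
        total = stats["signal"]
        assert abs(total - 500) <= 3 * np.sqrt(500) + 5

    def test_identical_config_gives_identical_sam(self, tmp_path):
        cfg = SimConfig(n_chroms=1, chrom_length=20_000, n_individuals=1, seed=8)
        genome = make_genome(cfg)
        truth = plant_truth(genome, cfg)
        simulate_reads(genome, truth.individuals[0], cfg, tmp_path / "a.sam")
        simulate_reads(genome, truth.individuals[0], cfg, tmp_path / "b.sam")
        assert (tmp_path / "a.sam").read_bytes() == (tmp_path / "b.sam").read_bytes()


class TestMakeAnnotations:
    def test_gene_tiling_and_counts(self, small_genome):
        features, genes, expr, escape = make_annotations(small_genome, genes_per_chrom=10, exons_per_gene=3)
        assert len(genes) == 10
        exons = [f for f in features if f.kind == "exon"]
        assert len(exons) == 30
        bodies = sorted(g.body for g in genes)
        assert all(a[1] <= b[0] for a, b in zip(bodies, bodies[1:]))

    def test_expression_quartiles_balanced(self, small_genome):
        from abaseq import ExpressionTable

        _, _, expr, _ = make_annotations(small_genome, genes_per_chrom=10)
        table = ExpressionTable.from_frame(expr)
        sizes = table.df["quartile"].value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_escape_scores_cover_range(self):
        cfg = SimConfig(n_chroms=2, chrom_length=200_000, seed=9)
        genome = make_genome(cfg)
        _, _, _, escape = make_annotations(genome, genes_per_chrom=30)
        assert set(escape["score"]) == set(range(10))
        assert set(escape["gene_id"]) == {g for g in escape["gene_id"] if g.startswith("chrX")}

    def test_too_small_genome_rejected(self):
        cfg = SimConfig(n_chroms=1, chrom_length=5000, seed=10)
        with pytest.raises(ValueError, match="cannot place"):
            make_annotations(make_genome(cfg), genes_per_chrom=50)
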