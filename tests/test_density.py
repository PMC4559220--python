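"""Density formulas and binned profiles."""

import numpy as np
import pytest

from abaseq import (
    CpgIndex,
    ExpressionTable,
    Feature,
    GeneModel,
    Genome,
    HmcSite,
    SiteSet,
    chromosome_density,
    exon_boundary_profile,
    feature_density,
    metagene_profile,
    peak_profile,
)

from conftest import siteset_at


@pytest.fixture
def unit_genome():
    # 1 kb chromosome with exactly 100 CGs at multiples of 10
    return Genome({"chr1": ("CG" + "AT" * 4) * 100})


class TestChromosomeDensity:
    def test_formula(self, unit_genome):
        sites = siteset_at([0, 10, 20, 30, 40, 50, 60, 70, 80, 90])
        (rec,) = chromosome_density(sites, unit_genome)
        assert rec.n_sites == 10 and rec.n_cg == 100 and rec.span_bp == 1000
        assert rec.density == pytest.approx(10 / (100 * 1000))

    def test_no_sites_zero_density(self, unit_genome):
        (rec,) = chromosome_density(SiteSet("empty"), unit_genome)
        assert rec.density == 0.0

    def test_zero_cg_chromosome_flagged(self):
        genome = Genome({"chrZ": "A" * 500})
        (rec,) = chromosome_density(siteset_at([], chrom="chrZ"), genome)
        assert not rec.defined

    def test_matches_brute_force(self, small_genome, small_index, rng):
        from conftest import plant_uniform

        sites = plant_uniform(small_index, 0.3, rng)
        (rec,) = chromosome_density(sites, small_genome, small_index)
        assert rec.density == pytest.approx(
            len(sites) / (small_index.total("chr1") * len(small_genome["chr1"]))
        )


class TestFeatureDensity:
    def test_formula_single_exon(self):
        idx = CpgIndex({"chr1": list(range(100, 200, 10))})
        features = [Feature("chr1", 100, 200, "exon")]
        sites = siteset_at([110, 150])
        (rec,) = feature_density(sites, features, idx)
        assert rec.density == pytest.approx(2 / (10 * 100))

    def test_boundary_site_excluded_half_open(self):
        idx = CpgIndex({"chr1": [150]})
        features = [Feature("chr1", 100, 200, "exon")]
        (rec,) = feature_density(siteset_at([200]), features, idx)
        assert rec.n_sites == 0

    def test_overlapping_intervals_merged(self):
        idx = CpgIndex({"chr1": [110, 160]})
        features = [Feature("chr1", 100, 180, "exon"), Feature("chr1", 150, 200, "exon")]
        (rec,) = feature_density(siteset_at([110]), features, idx)
        assert rec.span_bp == 100 and rec.n_cg == 2 and rec.n_sites == 1


class TestPeakProfile:
    def test_single_site_downstream_of_center(self):
        peaks = [Feature("chr1", 9000, 11000, "chip_peak")]  # center 10000
        pm = peak_profile(siteset_at([10050]), peaks)
        assert pm.values[30] == 1.0  # bin [0, 100) downstream of center
        assert pm.values.sum() == 1.0

    def test_duplicated_peaks_mean_invariant(self):
        peak = Feature("chr1", 9000, 11000, "chip_peak")
        sites = siteset_at([9500, 10050, 10400])
        one = peak_profile(sites, [peak])
        five = peak_profile(sites, [peak] * 5)
        np.testing.assert_allclose(one.values, five.values)

    def test_no_peaks_rejected(self):
        with pytest.raises(ValueError, match="no peaks"):
            peak_profile(siteset_at([1]), [])

    def test_mass_conservation(self, rng):
        peaks = [Feature("chr1", int(c) - 100, int(c) + 100, "chip_peak") for c in rng.integers(5000, 50_000, 20)]
        positions = sorted(int(p) for p in rng.choice(60_000, 500, replace=False))
        sites = siteset_at(positions)
        pm = peak_profile(sites, peaks)
        brute = sum(
            1
            for p in positions
            for pk in peaks
            if pk.center - 3000 <= p < pk.center + 3000
        )
        assert pm.values.sum() * len(peaks) == pytest.approx(brute)

    def test_order_invariance(self, rng):
        peaks = [Feature("chr1", int(c), int(c) + 200, "chip_peak") for c in rng.integers(5000, 50_000, 10)]
        positions = [int(p) for p in rng.choice(60_000, 200, replace=False)]
        a = peak_profile(siteset_at(sorted(positions)), peaks)
        b = peak_profile(siteset_at(positions), list(reversed(peaks)))
        np.testing.assert_allclose(a.values, b.values)


def _gene(gene_id="g1", chrom="chr1", strand="+", start=50_000, nexons=3, exon_len=500, intron_len=500):
    exons = tuple(
        (start + i * (exon_len + intron_len), start + i * (exon_len + intron_len) + exon_len)
        for i in range(nexons)
    )
    body = (exons[0][0], exons[-1][1])
    tss, tes = (body[0], body[1] - 1) if strand == "+" else (body[1] - 1, body[0])
    return GeneModel(gene_id, chrom, strand, tss, tes, exons, body)


class TestMetageneProfile:
    def test_site_at_tss_lands_in_first_body_bin(self):
        gene = _gene()
        expr = ExpressionTable({"g1": 1.0})
        profiles = metagene_profile(siteset_at([gene.tss]), [gene], expr)
        q = expr.quartile("g1")
        values = profiles[q].values
        assert values[50] > 0  # first body bin
        assert values[:50].sum() == 0

    def test_minus_strand_site_near_tes_flipped_to_3prime_end(self):
        gene = _gene(strand="-")
        expr = ExpressionTable({"g1": 1.0})
        profiles = metagene_profile(siteset_at([gene.body[0] + 1]), [gene], expr)
        values = profiles[expr.quartile("g1")].values
        assert values[50:100].argmax() >= 45  # 3'-most body bins

    def test_short_gene_skipped(self):
        gene = GeneModel("tiny", "chr1", "+", 100, 129, ((100, 130),), (100, 130))
        expr = ExpressionTable({"tiny": 1.0})
        profiles = metagene_profile(siteset_at([110]), [gene], expr)
        assert profiles[expr.quartile("tiny")].n_regions == 0


class TestExonBoundaryProfile:
    def test_only_internal_exons_used(self):
        g3 = _gene(nexons=3)
        sense, antisense = exon_boundary_profile(SiteSet("e"), [g3])
        assert sense.n_regions == 1
        g2 = _gene(nexons=2)
        sense2, _ = exon_boundary_profile(SiteSet("e"), [g2])
        assert sense2.n_regions == 0

    def test_first_base_of_internal_exon_sense_position_zero(self):
        gene = _gene(nexons=3)
        internal = gene.internal_exons[0]
        sites = SiteSet("x", [HmcSite("chr1", internal[0], "+")])
        sense, antisense = exon_boundary_profile(sites, [gene])
        # 5' block occupies indices 0..39; position 0 is index 20
        assert sense.values[20] == 1.0
        assert antisense.values.sum() == 0.0

    def test_minus_gene_transcript_orientation(self):
        gene = _gene(strand="-", nexons=3)
        internal = gene.internal_exons[0]
        # first exonic base in transcript order is the rightmost base
        sites = SiteSet("x", [HmcSite("chr1", internal[1] - 1, "-")])
        sense, _ = exon_boundary_profile(sites, [gene])
        assert sense.values[20] == 1.0

    def test_opposite_strand_goes_to_antisense(self):
        gene = _gene(nexons=3)
        internal = gene.internal_exons[0]
        sites = SiteSet("x", [HmcSite("chr1", internal[0], "-")])
        sense, antisense = exon_boundary_profile(sites, [gene])
        assert sense.values.sum() == 0.0
        assert antisense.values[20] == 1.0
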