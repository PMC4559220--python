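"""Cluster calling vs a graph-connectivity oracle, gene assignment, enrichment."""

from math import comb

import numpy as np
import pytest

from abaseq import (
    Cluster,
    ClusterConfig,
    GeneModel,
    HmcSite,
    SiteSet,
    assign_cluster_gene,
    call_clusters,
    enrich,
)

from conftest import siteset_at


def oracle_clusters(positions, max_gap=200, min_sites=3):
    """Independent oracle: build a graph joining every pair of sites within
    max_gap and take connected components (union-find)."""
    pos = sorted(positions)
    parent = list(range(len(pos)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(len(pos)):
        j = i + 1
        while j < len(pos) and pos[j] - pos[i] <= max_gap:
            union(i, j)
            j += 1
    comps = {}
    for i in range(len(pos)):
        comps.setdefault(find(i), []).append(pos[i])
    out = []
    for members in comps.values():
        if len(members) >= min_sites:
            out.append((min(members), max(members) + 1, len(members)))
    return sorted(out)


class TestCallClusters:
    def test_worked_example(self):
        ss = siteset_at([100, 250, 400, 700])
        (c,) = call_clusters(ss)
        assert (c.start, c.end, c.n_sites) == (100, 401, 3)

    def test_two_sites_no_cluster(self):
        assert call_clusters(siteset_at([100, 301])) == []

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(10, 2000))
            positions = np.unique(rng.integers(0, 200_000, size=n))
            found = call_clusters(siteset_at(positions.tolist()))
            got = sorted((c.start, c.end, c.n_sites) for c in found)
            assert got == oracle_clusters(positions.tolist())

    def test_strands_pooled(self):
        sites = SiteSet(
            "x",
            [HmcSite("chr1", 100, "+"), HmcSite("chr1", 200, "-"), HmcSite("chr1", 300, "+")],
        )
        (c,) = call_clusters(sites)
        assert c.n_sites == 3

    def test_sites_in_clusters_monotone_in_max_gap(self, rng):
        positions = np.unique(rng.integers(0, 50_000, size=500)).tolist()
        counts = []
        for gap in (400, 200, 100, 50):
            clusters = call_clusters(siteset_at(positions), ClusterConfig(max_gap=gap))
            counts.append(sum(c.n_sites for c in clusters))
        assert counts == sorted(counts, reverse=True)

    def test_clusters_disjoint_and_separated(self, rng):
        positions = np.unique(rng.integers(0, 100_000, size=2000)).tolist()
        clusters = call_clusters(siteset_at(positions))
        for a, b in zip(clusters, clusters[1:]):
            assert b.start - (a.end - 1) > 200

    def test_diameter_mode_caps_span(self, rng):
        positions = np.unique(rng.integers(0, 10_000, size=500)).tolist()
        clusters = call_clusters(siteset_at(positions), ClusterConfig(mode="diameter"))
        assert all(c.end - 1 - c.start <= 200 for c in clusters)


def _gene(gene_id, start, end, strand="+", chrom="chr1"):
    tss, tes = (start, end - 1) if strand == "+" else (end - 1, start)
    return GeneModel(gene_id, chrom, strand, tss, tes, ((start, end),), (start, end))


class TestAssignClusterGene:
    def test_within_body(self):
        cluster = Cluster("chr1", 1000, 1101, 3)
        out = assign_cluster_gene(cluster, [_gene("G", 500, 2000)])
        assert out.assigned_gene == "G" and out.assignment_mode == "within_body"

    def test_nested_genes_smallest_body_wins(self):
        cluster = Cluster("chr1", 1000, 1101, 3)
        genes = [_gene("outer", 0, 10_000), _gene("inner", 900, 1500)]
        assert assign_cluster_gene(cluster, genes).assigned_gene == "inner"

    def test_nearest_tss(self):
        cluster = Cluster("chr1", 100_000, 100_101, 3)
        genes = [_gene("near", 110_000, 112_000), _gene("far", 130_000, 132_000)]
        out = assign_cluster_gene(cluster, genes)
        assert out.assigned_gene == "near" and out.assignment_mode == "nearest_tss"

    def test_beyond_max_tss_distance_unassigned(self):
        cluster = Cluster("chr1", 0, 101, 3)
        out = assign_cluster_gene(cluster, [_gene("far", 300_050, 301_000)])
        assert out.assigned_gene is None and out.assignment_mode == "unassigned"

    def test_tss_tie_broken_lexicographically(self):
        cluster = Cluster("chr1", 10_000, 10_001, 3)  # midpoint 10000
        genes = [_gene("b", 11_000, 12_000), _gene("a", 8_001, 9_001, strand="-")]
        # both TSS at distance 1000 (a's '-' TSS is 9000, b's at 11000)
        assert assign_cluster_gene(cluster, genes).assigned_gene == "a"


class TestEnrich:
    def test_exact_hypergeometric_fixture(self):
        background = [f"g{i}" for i in range(20)]
        gene_list = background[:5]
        term_map = {"t": background[:4]}
        (res,) = enrich(gene_list, background, term_map)
        assert res.observed == 4
        assert res.expected == pytest.approx(5 * 4 / 20)
        assert res.p == pytest.approx(16 / 15504, rel=1e-12)
        assert res.direction == "up"

    def test_term_equals_list_equals_background(self):
        genes = [f"g{i}" for i in range(6)]
        (res,) = enrich(genes, genes, {"all": genes})
        assert res.p == pytest.approx(1.0)
        assert res.observed == res.expected

    def test_gene_missing_from_background_named(self):
        with pytest.raises(ValueError, match="ghost"):
            enrich(["ghost"], ["a", "b"], {"t": ["a"]})

    def test_bh_matches_direct_step_up(self):
        rng = np.random.default_rng(3)
        background = [f"g{i}" for i in range(200)]
        gene_list = [background[i] for i in rng.choice(200, 40, replace=False)]
        term_map = {
            f"term{j}": [background[i] for i in rng.choice(200, 30, replace=False)]
            for j in range(5)
        }
        results = enrich(gene_list, background, term_map)
        pvals = np.array([r.p for r in results])
        m = len(pvals)
        order = np.argsort(pvals)
        direct = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, pvals[i] * m / (rank + 1))
            direct[i] = running
        np.testing.assert_allclose([r.fdr for r in results], direct, rtol=1e-12)
        assert all(r.fdr >= r.p for r in results)

    def test_down_direction_uses_lower_tail(self):
        background = [f"g{i}" for i in range(20)]
        gene_list = background[10:15]
        term_map = {"t": background[:10]}  # observed 0, expected 2.5
        (res,) = enrich(gene_list, background, term_map)
        assert res.direction == "down"
        # P(X <= 0) = C(10,0)C(10,5)/C(20,5)
        assert res.p == pytest.approx(comb(10, 5) / comb(20, 5), rel=1e-12)
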