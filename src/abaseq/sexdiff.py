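"""Sex-specific 5hmC site sets, male-specific clusters, and X-inactivation
escape comparisons.

Female-unique sites are the union of female site sets minus the union of
male site sets. Male-specific clusters follow a subsampling scheme: several
random subsets of males are drawn, clusters are called on each subset's
male-unique sites (vs. all females), and only clusters recurring - by >= 1
bp overlap, or exact coordinates - in every subset are retained. Gene-body
5hmC density per CpG is compared across X-inactivation escape scores (0 =
fully inactivated ... 9 = complete escape) with a two-sided rank-sum test
of escaping (score >= 1) vs. inactivated (score 0) genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .clusters import Cluster, ClusterConfig, call_clusters
from .datamodel import CpgIndex, GeneModel, SiteSet

log = logging.getLogger(__name__)

__all__ = ["SexConfig", "female_unique_sites", "male_specific_clusters", "escape_density"]


@dataclass
class SexConfig:
    n_male_sets: int = 5
    male_set_size: int = 5
    seed: int = 0
    #: cluster matching across male subsets: 'overlap' (>= 1 bp) or 'exact'
    match_mode: str = "overlap"

    def __post_init__(self):
        if self.n_male_sets < 1 or self.male_set_size < 1:
            raise ValueError("need n_male_sets >= 1 and male_set_size >= 1")
        if self.match_mode not in ("overlap", "exact"):
            raise ValueError("match_mode must be 'overlap' or 'exact'")


def female_unique_sites(
    female_sets: Sequence[SiteSet], male_sets: Sequence[SiteSet]
) -> SiteSet:
    """Union of female sites minus the union of male sites."""
    if not female_sets or not male_sets:
        raise ValueError("need at least one female and one male site set")
    female_union: set = set()
    for ss in female_sets:
        female_union |= ss.keys()
    male_union: set = set()
    for ss in male_sets:
        male_union |= ss.keys()
    unique = female_union - male_union
    assert not unique & male_union
    return SiteSet.from_keys(unique, "female_unique", sex="F")


def _matches(c: Cluster, others: Sequence[Cluster], mode: str) -> bool:
    if mode == "exact":
        return any(o.chrom == c.chrom and (o.start, o.end) == (c.start, c.end) for o in others)
    return any(c.overlaps(o) for o in others)


def male_specific_clusters(
    male_sets: Sequence[SiteSet],
    female_sets: Sequence[SiteSet],
    cluster_cfg: Optional[ClusterConfig] = None,
    sex_cfg: Optional[SexConfig] = None,
) -> list[Cluster]:
    """Clusters of male-unique sites recurring in every random male subset.

    For each of ``n_male_sets`` seeded draws of ``male_set_size`` males
    (without replacement within a draw; draws may overlap), clusters are
    called on the subset's site union minus the female union. A cluster
    from the first draw is male-specific iff a matching cluster appears in
    every draw. Deterministic given the seed.
    """
    cluster_cfg = cluster_cfg or ClusterConfig()
    sex_cfg = sex_cfg or SexConfig()
    if len(male_sets) < sex_cfg.male_set_size:
        raise ValueError(
            f"need >= {sex_cfg.male_set_size} males, have {len(male_sets)}"
        )
    if not female_sets:
        raise ValueError("need at least one female site set")
    female_union: set = set()
    for ss in female_sets:
        female_union |= ss.keys()

    rng = np.random.default_rng(sex_cfg.seed)
    per_set_clusters: list[list[Cluster]] = []
    for s in range(sex_cfg.n_male_sets):
        idx = rng.choice(len(male_sets), size=sex_cfg.male_set_size, replace=False)
        subset_union: set = set()
        for i in idx:
            subset_union |= male_sets[int(i)].keys()
        unique = subset_union - female_union
        assert not unique & female_union
        subset_sites = SiteSet.from_keys(unique, f"male_subset_{s}")
        per_set_clusters.append(call_clusters(subset_sites, cluster_cfg))

    candidates = per_set_clusters[0]
    retained = [
        c
        for c in candidates
        if all(_matches(c, others, sex_cfg.match_mode) for others in per_set_clusters[1:])
    ]
    return retained


def escape_density(
    female_sets: Sequence[SiteSet],
    genes: Sequence[GeneModel],
    escape_scores: Mapping[str, int],
    cpg_index: CpgIndex,
    region: str = "body",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Gene-body 5hmC per CpG for X-linked genes, grouped by escape score.

    Uses the union of all female sites (strands pooled). Returns a per-gene
    table, per-score group means, and a two-sided rank-sum (Mann-Whitney)
    test of escaping (score >= 1) vs. inactivated (score 0) genes.
    Genes without a CG in the region are skipped with a logged count.
    """
    if region != "body":
        raise ValueError("only region='body' is implemented")
    union: set = set()
    for ss in female_sets:
        union |= ss.keys()
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos, _ in union:
        by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[arg-type]
    by_chrom = {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in by_chrom.items()}

    rows = []
    skipped = 0
    for gene in genes:
        if gene.gene_id not in escape_scores:
            continue
        start, end = gene.body
        n_cg = cpg_index.count(gene.chrom, start, end)
        if n_cg == 0:
            skipped += 1
            continue
        arr = by_chrom.get(gene.chrom, np.empty(0, dtype=np.int64))
        n_sites = int(np.searchsorted(arr, end, "left") - np.searchsorted(arr, start, "left"))
        rows.append(
            {
                "gene_id": gene.gene_id,
                "score": int(escape_scores[gene.gene_id]),
                "n_sites": n_sites,
                "n_cg": n_cg,
                "density": n_sites / n_cg,
            }
        )
    if skipped:
        log.info("escape_density: skipped %d genes without a CG in the body", skipped)
    per_gene = pd.DataFrame(rows)
    if per_gene.empty:
        raise ValueError("no scored genes with CGs found")
    groups = (
        per_gene.groupby("score")["density"].agg(["mean", "count"]).reset_index()
    )
    inactive = per_gene.loc[per_gene["score"] == 0, "density"].to_numpy()
    escaping = per_gene.loc[per_gene["score"] >= 1, "density"].to_numpy()
    test: dict = {
        "n_inactivated": int(inactive.size),
        "n_escaping": int(escaping.size),
    }
    if inactive.size and escaping.size:
        if np.all(inactive == inactive[0]) and np.all(escaping == escaping[0]) and inactive[0] == escaping[0]:
            test.update({"statistic": float("nan"), "p": 1.0})
        else:
            stat, p = mannwhitneyu(escaping, inactive, alternative="two-sided")
            test.update({"statistic": float(stat), "p": float(p)})
        mean_in = float(inactive.mean())
        test["mean_ratio"] = float(escaping.mean() / mean_in) if mean_in > 0 else float("inf")
    else:
        test.update({"statistic": float("nan"), "p": float("nan"), "mean_ratio": float("nan")})
    return per_gene, groups, test
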