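# abaseq

Single-base 5-hydroxymethylcytosine (5hmC) analysis from AbaSI
restriction-digest sequencing (AbaSI-Seq).

5hmC is the TET-oxidation product of 5-methylcytosine, particularly
abundant and dynamic in brain tissue, and found almost exclusively in CpG
context. AbaSI-Seq localizes it at single-base resolution without
bisulfite conversion: the AbaSI enzyme recognizes glucosyl-5hmC and cleaves
11–13 bp downstream, so after adaptor ligation and single-end sequencing
the modified cytosine sits at a fixed small offset from each read's 5'
end. This package implements the computational arc of such a study for
cohorts of unrelated individuals:

* **site calling** — from aligned reads, test read offsets *d* ∈ {11, 12, 13}
  (ascending; first CpG match wins) against the reference; a hit yields a
  strand-aware single-base call at the plus-strand C of the CpG. Reads are
  pre-filtered on mean base quality (> 30) and MAPQ (≥ 10).
* **multi-individual consensus** — per-site carrier counts with stringency
  tiers at ⌈f·n⌉ individuals for f = 0.25 / 0.50 / 0.75 (thresholds 5 / 10 / 15
  for n = 19).
* **overlap statistics** — for samples with K and n sites sharing k of an
  N-site universe, the upper tail P(X ≥ k), X ~ Hypergeometric(N, K, n),
  summed in log space from log-gamma terms so that values far below linear
  float underflow (log₁₀P ≈ −3×10⁵ at cohort scale) remain exact.
* **densities and profiles** — per-chromosome and per-feature-kind density
  n_sites / (n_CG × length); 100 bp-binned profiles ±3 kb around ChIP-peak
  centers; 50-bin metagene profiles with 20 kb flanks per expression
  quartile; per-base sense/antisense profiles ±20 bp around internal
  exon–intron boundaries.
* **clusters and enrichment** — maximal runs of ≥ 3 sites with consecutive
  gaps ≤ 200 bp, assigned to the containing gene body or the nearest TSS
  within 250 kb; hypergeometric term enrichment with Benjamini–Hochberg FDR.
* **sex comparisons** — female-unique sites (female union minus male
  union), male-specific clusters recurring across 5 random sets of 5 males,
  and gene-body 5hmC per CpG across X-inactivation escape scores (0 =
  inactivated … 9 = complete escape) with a rank-sum test.

A first-class synthetic-data module generates seeded genomes, cohorts with
a shared-core-plus-private-sites structure, AbaSI-geometry reads (SAM) and
annotation/expression/escape fixtures, so the full pipeline is testable
end to end with no external data.

## Worked example

```python
import tempfile, numpy as np
from pathlib import Path
from abaseq import *
from abaseq import io as aio

cfg = SimConfig(n_chroms=1, chrom_length=100_000, cpg_rate=0.02,
                n_individuals=19, noise_read_rate=0.0, seed=1)
genome = make_genome(cfg)
truth = plant_truth(genome, cfg)
workdir = Path(tempfile.mkdtemp())
rng = np.random.default_rng(1)
called = []
for ss in truth.individuals:
    sam = workdir / f"{ss.individual_id}.sam"
    simulate_reads(genome, ss, cfg, sam, rng=rng)
    reads = filter_reads(aio.read_alignments(sam, genome), CallerConfig())
    called.append(call_sites(reads, genome, CallerConfig(), ss.individual_id))

recovered = all(c.keys() == t.keys() for c, t in zip(called, truth.individuals))
print(f"exact recovery in all 19 subjects: {recovered}")

table = build_consensus(called)
print(f"union sites: {len(table)}")
for tier in ("low", "intermediate", "high"):
    subset = stringency_subset(table, tier=tier)
    print(f"{tier:>12} tier (>= {StringencyConfig().min_count(tier, 19):2d} of 19): {len(subset)} sites")

clusters = call_clusters(stringency_subset(table, tier="intermediate"))
print(f"clusters (>=3 sites, gaps <=200 bp): {len(clusters)}")

test = overlap_hypergeometric(K=6_793_582, n=3_818_749, k=1_999_493, N=27_000_000)
print(f"overlap log10 P = {test.log10_p:.1f}")
```

prints

```
exact recovery in all 19 subjects: True
union sites: 945
         low tier (>=  5 of 19): 400 sites
intermediate tier (>= 10 of 19): 400 sites
        high tier (>= 15 of 19): 400 sites
clusters (>=3 sites, gaps <=200 bp): 52
overlap log10 P = -335541.9
```

With no sequencing noise every planted site is recovered in every subject.
The cohort's 945-site union splits into a 400-site core carried by all 19
subjects and private sites carried by one or two, so every stringency tier
resolves to the core (the generator's sharing spectrum is bimodal by
construction — see `docs/methods.md`). The final line scores the overlap
between two samples of 6.79 M and 3.82 M sites sharing 2.00 M of a 27 M
universe: a log₁₀ probability near −335 542, i.e. overwhelming evidence
that shared 5hmC positions across individuals are not chance.

A `abaseq` console script exposes the same steps
(`simulate`, `call`, `consensus`, `overlap`, `density`, `clusters`,
`enrich`, `sexdiff`, `pipeline`); `abaseq pipeline --config run.yaml` runs
everything from one config and writes a manifest with per-output SHA-256
hashes for reproducibility.

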