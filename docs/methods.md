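# Methods

## The measurement model

AbaSI-Seq reduces 5hmC detection to a geometric inference. The AbaSI
enzyme binds glucosylated 5hmC and cleaves 11–13 bp downstream of the
modified cytosine; adaptors are ligated at the cut, so the 5' end of a
sequenced read sits a known small distance from the mark. The caller
inverts this geometry: for each aligned read it computes, for each offset
d ∈ {11, 12, 13} in ascending order, the reference position d bases into
the read from its 5' aligned end *on the read's own strand*, and emits a
call if the reference shows a CpG in the read's orientation there. The
first matching offset wins and later offsets are not tested; this
tie-break is a package choice — with multiple candidate CpGs per read the
assay itself is ambiguous, and a deterministic documented rule is
preferable to an arbitrary one. Reads without a CpG at any tested offset
carry no information and are discarded, mirroring the expectation that a
large fraction of digest reads are uninformative.

Coordinates are 0-based half-open throughout. A site's position is always
the plus-strand C of its CpG; the strand field records which strand is
modified. The two strands of one CpG are therefore distinct sites with
equal positions, and a `merge_strands` option collapses them when
symmetric hydroxymethylation should be treated as one event (off by
default, since per-strand occupancy is what the assay measures).

Read-level filters follow the protocol's two quality gates: mean base
quality strictly greater than 30 (the mean is our choice of statistic;
the underlying filter is stated only as "quality score") and mapping
quality at least 10 (inclusive). Duplicate collapsing — one read per
(chromosome, start, strand), highest MAPQ then lexicographic read name —
is available for inputs that were not already deduplicated upstream.
Reads with indels or clipping are skipped with a logged count: the caller
assumes ungapped alignments, which the simulator guarantees and which
real users must provide (realignment is out of scope).

## Cohort consensus and the overlap statistic

The consensus table counts carriers per site. Stringency tiers keep sites
carried by at least ⌈f·n⌉ individuals, f = 0.25/0.50/0.75; for n = 19 this
gives 5/10/15, matching the convention of "sites common to ~25/50/75 % of
the sample". The ceiling rule is the only rounding that reproduces all
three thresholds at n = 19.

Two-sample overlap is scored as P(X ≥ k) for X ~ Hypergeometric(N, K, n)
with N defaulting to 27 million — an estimate of the total brain 5hmC
site universe. At K, n in the millions linear-space probabilities
underflow and naive summation is infeasible, so the tail is accumulated in
log space: the log-pmf at the anchor term comes from log-gamma, successive
terms from the exact pmf ratio, and a running log-sum-exp stops when a
term changes the total by < 1e-12 relatively. When k lies at or below the
distribution's mode (where the upper tail is large and the term sequence
would first grow), the complementary lower tail is accumulated downward
instead and converted via log1p. The implementation is cross-checked
against exhaustive enumeration for every feasible configuration with
N ≤ 12 and against `scipy.stats.hypergeom` spot values; scipy itself is
not usable as the implementation because its linear-space survival
function underflows to zero exactly where this statistic matters.

## Densities and profiles

Density is n_sites / (n_CG × span): site counts corrected for both CG
content and length by simple division. The normalization algebra is not
uniquely determined by "corrected for"; the product form is stated in
output headers so alternatives can be compared. Intervals of one feature
kind are merged before counting, so overlapping annotations are not
double-counted; sites are strand-pooled for all density and profile
computations.

Profiles use three schemes. Peak profiles: 60 contiguous 100 bp bins
spanning ±3 kb around each peak's center (start + ⌊len/2⌋ for even
lengths), averaged over peaks (so duplicating a peak changes nothing);
windows truncated at a chromosome edge contribute their truncated counts
and are flagged. Metagene profiles: per expression quartile (rank-based
quartiles, sizes equal ±1), 50 fixed 400 bp bins on each 20 kb flank and
50 width-proportional bins across the gene body, per-gene values are
counts per bp, genes weigh equally in the quartile mean (per-gene
averaging, not pooling, so long genes do not dominate), and minus-strand
genes are flipped so bin 0 is always 5'-most; the TSS base belongs to the
first body bin. A `per_cpg` flag divides bin counts by bin CG content
instead of width. Exon-boundary profiles: per-base counts ±20 bp around
the 5' and 3' boundaries of internal exons (first and last exons and
single-exon genes excluded; genes need ≥ 3 exons to contribute),
transcript-oriented, split by whether the site's strand matches the gene
(sense) or not (antisense).

Clusters are maximal single-linkage runs: consecutive strand-pooled sites
≤ 200 bp apart chain together and runs of ≥ 3 sites are emitted. The
alternative reading — pairwise span ≤ 200 bp — is available behind
`mode="diameter"`, but chaining is the standard reading of "each within
200 bp of each other" and is the default. Cluster midpoints (coordinate
midpoint, not site median) are assigned to the smallest containing gene
body, else the nearest TSS (ties broken by gene name) within 250 kb.
Enrichment is a flat hypergeometric test per term (no ontology traversal
— term semantics belong to the annotation, not the statistic) with BH
step-up across terms via statsmodels and significance at FDR ≤ 0.05. The
default directional rule tests the upper tail when observed ≥ expected
and the lower tail otherwise; note that this two-branch p-value is *not*
uniform under the null (its CDF is ≈ 2t for small t), so calibration
checks use the one-sided `alternative="greater"` mode.

## Sex comparisons

Female-unique sites are the female union minus the male union, asserted
disjoint from the male union. Male-specific clusters: several seeded
random subsets of males are drawn (without replacement within a subset;
subsets may overlap), clusters are called on each subset's sites minus the
female union, and clusters from the first subset that have a ≥ 1 bp
overlapping counterpart in every subset are retained (exact-coordinate
matching is available; an overlap rule is the package's choice since no
matching rule is inherent to the design). Escape comparison: per X-linked
gene, gene-body sites per body CG from the pooled female union; groups by
escape score 0–9; a two-sided Mann-Whitney rank-sum test contrasts
escaping (score ≥ 1) against inactivated (score 0) genes. The rank-sum
test and the per-CpG rate are choices: densities are non-negative,
zero-inflated and heteroskedastic, which rules out a t-test on raw rates.

## The synthetic-data generator

The generator emulates the study conditions, not the wet protocol.
Genomes are i.i.d. background bases with chance CG dinucleotides removed
and exactly ⌊rate·length⌋ CGs injected at uniformly random positions with
pairwise start spacing ≥ 3 bp. The spacing serves correctness of the
fixtures: it guarantees that a read generated for a CpG at offset d can
never present a different CpG at a smaller tested offset, so the
first-match rule resolves every noise-free read to its true site and
exact recovery is a meaningful test. Consequences: no CpG islands of
adjacent CGs, and CG density is uniform rather than clustered — real
genomes violate both, so flat-profile tests certify the estimator, not
genome realism.

Cohorts follow a shared-core-plus-private model: a core fraction (default
0.2) of the eligible CpG pool is given to every individual with a fixed
per-site strand, and each individual independently adds private sites at
a per-CpG rate (default 0.02) with random strands. The resulting sharing
spectrum is bimodal (carried by all, or by very few); the graded sharing
spectrum of real cohorts would need correlated per-site carrier
probabilities, which the model deliberately omits — tiers collapsing to
the core on default synthetic data is expected behavior. Per-site read
counts are Poisson with mean `reads_per_site` (default 5) truncated at
one read, so every planted site is observable and noise-free recovery is
exact rather than probabilistic; the truncation shifts the mean by
+P(0 reads) ≈ 0.7 % at the default, negligible for count checks. Signal
reads get MAPQ 42 and uniform Q40 base qualities; background reads
(default 1 per kb; 0 disables) are uniform in position and strand with
MAPQ uniform on 0–42, so roughly a quarter fail the MAPQ gate. Offset
weights default to {11: 0.25, 12: 0.5, 13: 0.25} — only the 11–13 range
is given by the assay; the shape is a package default. Sequencing errors,
PCR duplicates and indels are not modeled.

Annotations are tiled non-overlapping multi-exon genes on alternating
strands, CpG islands over the most CG-dense windows, enhancers and ChIP
peaks in intergenic gaps, log-normal expression, and escape scores
cycling 0–9 over genes on the designated X chromosome (the last
chromosome of a multi-chromosome genome is named `chrX`).

## Numerical and testing choices

Problem sizes in the test suite are chosen so that stochastic assertions
have comfortable margins at fixed seeds: 100 kb genomes at 2 % CG for
recovery tests (≈ 2,000 CpGs, ≈ 430 sites and ≈ 2,200 reads per subject);
a 720 kb genome at 5 % CG with 160 four-exon genes for profile tests, so
flat-profile bins expect ≥ 200 sites (max/min ratio bound 1.5) and the 5×
gene-body enrichment estimate has ≈ 6 % relative noise against a [4, 6]
acceptance band. Per-position sense/antisense symmetry is checked at 3σ
with an allowance of ≤ 2 % violating positions: with ~160 independent
positions, ~0.3 % chance excursions beyond 3σ are expected, so an
all-positions hard bound would fail a third of seeds by chance; a 5σ hard
cap still catches real asymmetry. The enrichment-calibration KS test uses
a 20,000-gene background with 2,000-gene draws so the discrete
hypergeometric support is fine enough for a continuous-uniform reference.

Degenerate inputs: chromosomes with zero CGs or zero span yield flagged
undefined densities; genes with bodies shorter than the bin count are
skipped with a logged count; QC correlations with fewer than three
individuals or zero-variance covariates are reported as undefined rather
than raising; identical escape-density groups report p = 1 without
invoking the rank-sum machinery.

## Known limitations

Alignment, duplicate marking against a real aligner, base-quality
recalibration and quantitative (β-value-style) hydroxymethylation levels
are out of scope; sites are present/absent per individual. The simulator's
genome and cohort models are deliberately simple (see above), so passing
tests certify algorithmic correctness under controlled conditions, not
performance on real brain data. Cohort-scale numbers from real studies
(tens of millions of union sites, chromosome-level density patterns)
require the human genome and real libraries and are not reproduced here.
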