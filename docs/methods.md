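# Methods

This note documents the models implemented in `triplome`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing its
output.

## Binomial methylation calling

Bisulfite sequencing converts unmethylated cytosines to uracil; methylated
cytosines are protected. Per cytosine the data are `k` methylated reads of
`n` total (per strand; strands are tested independently, matching per-strand
depth reporting). Conversion is imperfect: an unmethylated cytosine reads
methylated with the non-conversion probability `e`, estimated by pooling all
cytosines of an unmethylated spike-in control, `ê = Σk/Σn`. The pooled
estimator is the maximum-likelihood estimator under a shared error rate, and
its binomial standard error is reported via the total control read count.

Each site with `n ≥ min_depth` gets the exact binomial upper tail
`p = P(X ≥ k | n, ê)` (evaluated as `scipy.stats.binom.sf(k-1, n, e)`, which
matches a term-by-term summation to < 1e-12 for all `n ≤ 50`). Multiple
testing is controlled with Benjamini–Hochberg across all tested sites of
all contexts jointly — the discovery set is a p-value threshold set, so ties
at the threshold are all called; a per-context correction is available by
flag. Status is `methylated` iff `q < α` (default 0.05), `untested` iff
`n < min_depth`.

Choices:

* `min_depth = 1` by default. Calling from a single read is harmless under
  the binomial test (a 1/1 site has `p = e`, which rarely survives FDR
  control); excluding shallow sites is a summarisation decision, so
  denominators downstream state their own `min_depth`.
* Contexts truncated by a chromosome end (fewer than two downstream bases)
  default to CHH, the asymmetric class; this affects O(1) sites per
  chromosome.

## Methylome summaries

The primary level statistic is the **site fraction**: methylated / tested
sites. A read-weighted alternative (`Σk/Σn`) is available by flag; the two
differ when depth correlates with methylation. Per-feature levels accept
either gene parts (promoter, UTRs, exons, introns, downstream) or gene
categories; a site overlapped by several intervals of one class counts
once for that class.

Conventions: promoter = 2,000 bp upstream of the annotated gene start,
downstream = 2,000 bp past the gene end (no widths are standard; 2 kb is
the common plant-genomics default and matches the metagene flank width).
Metagene profiles bin fixed-width flanks at 100 bp and rescale the gene
body to 40 bins; minus-strand genes are flipped. Aggregation is
per-gene-then-mean so deeply covered genes do not dominate (pooled-site
aggregation by flag; the two coincide when genes contribute equal tested
site counts). Genes shorter than the body bin count are skipped and
counted. Genome tracks use non-overlapping 500-kb windows, keeping the
final partial window; empty bins are missing values, not zeros.

One false-positive caveat worth knowing: with FDR control at 5%, a small
number of truly unmethylated sites is called methylated. For a rare
context (CHH at ~2%) this inflates the recovered level by a few hundredths
of a percentage point — visible only when the site count is large enough
that the binomial standard error drops below that inflation.

## Synteny, chaining and fractionation

Anchors live in **gene-order coordinates** (index of the gene on its
chromosome), which is robust to intergenic length variation. The chain
search is a longest-path dynamic programme on the DAG of anchors:
transitions require strictly increasing query index and strictly
increasing (or decreasing, for inverted chains) target index, with both
index gaps ≤ `max_gap_genes` (default 10); chain score = Σ anchor scores −
`gap_penalty` × Σ skipped genes. Because the best short chain need not be a
prefix of the best chain of the required length, the DP state includes the
chain length capped at `min_anchors` (default 5). Chains are extracted
best-first; each anchor serves at most one chain. Queries claimed by
several chains stay only in the strongest chain, and chains falling below
`min_anchors` are deleted.

`gap_penalty` defaults to **0.25 per skipped gene** (anchor score 1).
A penalty matching the anchor score makes extension unprofitable wherever
mean retention is below ~0.5 — at retention 0.30 the expected skip cost per
extension (~2.3 genes) would exceed the anchor gain, shattering block
copies into fragments and discarding most true anchors. At 0.25, extension
pays for up to four skipped genes per anchor, which covers the gap
distribution implied by retention rates down to ~0.2 while still
penalising spurious long-range jumps.

Hit filtering keeps `E ≤ 1e-20` and bit score within the top 40% margin
below the query's best (`bit ≥ 0.6 × best`); the alternative reading (top
40% quantile of a query's hits) is selectable by flag.

Block copies are ranked by retained-anchor fraction; rank 1 → LF, 2 → MF1,
3 → MF2, extras flagged unassigned. Chains sharing a block and a query
chromosome count as one (possibly fragmented) copy. A curated external
partition table can override the ranking. Note the statistical limit of
rank-based labelling: distinguishing retention 0.35 from 0.30 by observed
fractions needs on the order of a thousand genes per block before the rank
swap probability per block drops below ~1%; the label-recovery validation
therefore simulates 1,000 genes per block across 24 blocks.

Gene categories: anchor members are `syntenic`; genes with no homology hit
at all are `species_specific`; genes with homology but no syntenic
position are `non_syntenic` (inside or outside block intervals — recorded
separately). Two genes hitting a common target on one chromosome with ≤ 5
intervening genes are flagged `tandem` (a flag, not a category; no
standard separation threshold exists, 5 is this package's choice).

## Dominance and functional diversification

Expression tables are transformed `y = ln(FPKM + 1)` and analysed
unreplicated: 3 sub-genomes × 4 tissues. Without replication the G×T
interaction is confounded with error, so the one-degree-of-freedom
non-additivity test is used; it targets interactions of the multiplicative
form `λ·G_i·T_j` and is exact (F on (1, 5) df) under the additive Gaussian
null. Degenerate tables — zero row or column variance, or residual sum of
squares entirely absorbed by the non-additivity term (relative tolerance
1e-12) — are reported with `p = 1` and a degenerate flag. Note this maps a
*perfectly* multiplicative noiseless table to `p = 1` as well; the flag is
what distinguishes "no evidence" from "no residual degrees of freedom".
The statistic is invariant under global affine transforms of the table but
**not** under per-row or per-column shifts, which alter the main effects
whose product defines the non-additivity direction.

The most highly expressed sub-genome is the row with the largest mean over
tissues; exact ties (a measure-zero event on real data) resolve in the
fixed order LF > MF1 > MF2 and are flagged. The cumulative dominance curve
sorts triplets by ascending p (ties by triplet id) and tracks cumulative
label shares, which sum to 1 at every rank.

Clustering uses `d = 1 − r` (Pearson) on per-gene tissue profiles —
zero-variance genes are filtered and counted first — with average linkage
(`scipy.cluster.hierarchy.linkage`; an independent O(n³) re-computation
oracle guards it in the tests). The tree is cut by taking memberships
after exactly `n − k` merges, which always yields exactly `k` clusters and
is deterministic given input order; cluster indices follow first gene
occurrence. Triplet separation is reported two ways — the fraction of
clustered triplet-member genes in triplets whose members do not all share
a cluster (primary), and the fraction of such triplets (secondary) —
because the headline "fraction separated" is ambiguous between the two.
Triplets with fewer than two clustered members are excluded.

## Gene-family expansion

Per family with counts `o_s` over four species and proteome totals `N_s`,
expected counts are `E_s = (Σo) · N_s/ΣN` (proportional-share null; an
equal-shares null by flag), `χ² = Σ (o−E)²/E` on 3 df, Bonferroni across
tested families, and the expanded species is the largest positive Pearson
residual `(o−E)/√E` among families significant after correction. Families
with zero total are skipped; families with any `E_s < 1` are flagged as
unreliable for the χ² approximation (no exact-test fallback).

## Half-tetrad centromere mapping

The generator simulates a four-strand bivalent: crossover count ~
Poisson(2L) for a map of L Morgans, positions uniform on the map, each
crossover joining one chromatid of each homolog chosen uniformly (no
chromatid or crossover interference — Haldane). An FDR gamete takes one
chromatid from each homolog, so both parental centromeres are present.
Marker alleles are resolved by tracing junctions outward from the
centromere.

Under this model the second-division-segregation frequency at map distance
x is Mather's classical `y(x) = (2/3)(1 − e^(−3x))`, and an FDR progeny is
heterozygous with probability

    h(x) = 1 − y/2 = (2 + e^(−3x)) / 3,

decaying from 1 at the centromere to an asymptote of **2/3** (not 1/2: the
two gamete chromatids do not recombine independently — a single crossover
can involve both, and the resulting parity coupling yields the 2/3 floor).
The simulation is validated against this closed form.

The estimator smooths the per-marker heterozygosity profile with a moving
average (window 5, in marker-index space — robust to uneven marker
density; bp-space smoothing by flag) and takes the argmax, resolving tied
runs to their midpoint; the support interval is the contiguous run within
`support_drop` (default 0.05) of the maximum. Profiles whose total range
is below `support_drop` are flagged flat with no estimate. Missing
genotypes are excluded from denominators, never imputed. The estimator is
validated purely by simulation (within ±2 marker spacings of truth in
≥95% of runs at 49 progeny, 50 markers, 2 Morgans).

## Triplet integration

Gene-body methylation means exons + introns. Expression vs gene-body mCG
uses 10 equal-width bins on [0, 1] with median/quartiles of `ln(FPKM+1)`
(z-scored across genes by default). The sub-genome comparison uses
Kruskal–Wallis (distribution-free; one-way ANOVA by flag) per context.
The triplet correlation matrix is 12 variables (3 copies × {FPKM, mCG,
mCHG, mCHH}) correlated across triplets; its display ordering is the
angular order of variables in the plane of the first two eigenvectors of
the correlation matrix (the corrgram convention), with each eigenvector's
sign fixed so its first nonzero loading is non-negative — making the
ordering deterministic. The leaf tissue joins the methylome by default
(configurable).

## The synthetic-data generator

Defaults encode the study conditions the package validates against: mean
per-strand depth 7.29 (Poisson), genome-wide methylation levels
CG/CHG/CHH = 0.55/0.09/0.02, non-conversion 0.005 (a free parameter — no
realised spike-in rate is standard; 0.5% is typical of modern bisulfite
kits), retention 0.50/0.35/0.30 per sub-genome, four tissues, and a
49-plant FDR mapping population. Site methylation is Bernoulli per site
(all-or-nothing), matching the binomial read model; a mosaic mode using
the level as a continuous per-site fraction is available but off by
default. Zero-coverage sites are emitted; exclusion is a downstream
decision. The expression model is `y = μ + G + T + GT + ε` on the
transformed scale with GT either zero, multiplicative (`σ_GT · G_i·T_j`),
or free Gaussian, plus an optional LF shift; FPKM = `exp(y) − 1` clipped
at 0. FASTA is written at 60 columns; GFF3 coordinates are 1-based
inclusive; every generator is bit-for-bit reproducible from one seed, with
independent streams per stage.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: sequence-composition structure (CpG
islands, repeats and their hypermethylation), read-level artefacts
(mapping bias, PCR duplicates, strand-coverage asymmetry), spatially
correlated methylation along the chromosome, dosage-dependent expression
correlations between tissues, selection on retained genes (retention is
independent Bernoulli per gene), and crossover interference. The FPKM
clip at zero slightly perturbs additivity on the transformed scale, so
generator-based null rejection rates of the Tukey test run a fraction of
a percentage point above nominal at the default μ; the test's calibration
itself is checked on the exact additive Gaussian null.

## Problem sizes and runtime

Validation problem sizes were chosen so the full suite runs in about a
minute: methylome checks on 0.3–2 Mb genomes (1e5 sites per context for
level recovery), 10,000 triplets for test calibration, 24 blocks × 1,000
genes for label recovery, 200 random instances for each oracle-equivalence
check (chains ≤ 15 anchors, clustering n = 30), and 100 replicate meioses
for centromere recovery. The acceptance script re-runs all of these from
scratch in well under a minute on one CPU.

## Known limitations

* No differential methylation between samples; one methylome at a time.
* Strand merging for symmetric contexts (CG/CHG) is not implemented;
  strands are independent observations throughout.
* The χ² family test has no exact fallback for small expected counts.
* The centromere estimator's support interval is descriptive, not a
  confidence interval.
* Sub-genome labels are exchangeable between equally fractionated copies;
  with fewer than a few hundred genes per block, MF1/MF2 ranks swap with
  appreciable probability.
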