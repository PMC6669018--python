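# Methods

This note documents the models, conventions, and design choices behind
`olfatlas`: what each stage computes, the parameters that matter, what the
synthetic-data generators do and do not emulate, and the numerical
decisions taken where the underlying procedure admits more than one
reasonable reading.

## Biological model and scope

Each mature olfactory sensory neuron (OSN) expresses a single olfactory
receptor (OR) gene, so in bulk RNA-seq of whole olfactory mucosa (WOM) the
normalized expression of a receptor is proportional to the number of OSNs
of that subtype. The pipeline quantifies these subtype abundances per
species, compares them across species through ortholog gene groups (OGGs),
and asks whether the most abundant subtypes are biased toward ecologically
relevant ligand classes — key food odorants (KFOs) or semiochemicals
(SMCs). The package consumes alignment hit tables, count matrices,
orthology tables, OR–ligand pair tables and descriptor matrices; it does
not run aligners or read summarizers, estimate dispersions or Wald tests
for differential expression, build phylogenies, or compute molecular
descriptors from structures.

## Annotation construction (`or_annotation`)

OR repertoires are poorly represented in base annotations, so curated OR
models aligned back to the genome are merged into the base GTF:

1. **Identity filter.** Percent identity is
   `100 · matches / (matches + mismatches + query_gap_bases)`; hits with
   identity strictly below the threshold (default 95%) are removed. The
   formula penalizes query-side gaps without target-side bookkeeping; the
   comparison is documented as strict-`<` so a hit at exactly 95% survives.
2. **Multimapper removal.** Every hit of any receptor retained at more
   than one locus is removed.
3. **Overlap resolution.** Overlap means ≥ 1 shared base on the same
   chromosome, strand-agnostic by default (a `strand_aware` flag exists).
   Within each overlap-connected component the highest-identity hit is
   kept, hits overlapping it are discarded, and the rule is reapplied to
   the remainder — so in a chain A–B–C with A best, C survives if it does
   not touch A. Exact identity ties are broken by a seeded uniform draw;
   with no ties the output is seed-independent.
4. **Merge.** Any base record overlapping a surviving hit (any feature
   type) is replaced by the OR record; non-overlapping hits are appended.
   Internally coordinates are 0-based half-open; GTF I/O converts to
   1-based inclusive at the boundary (`start_gtf = start + 1`,
   `end_gtf = end`). The `MergeReport` accounts for every input hit exactly
   once, and merging an already-merged annotation with the same survivors
   is a no-op.

OR models are single intervals (intronless-CDS convention).

## Quantification (`quantify`)

Size factors use the median-of-ratios estimator: for sample *s*, the
median over genes of `counts[g,s] / geomean_g`, excluding genes with any
zero (geometric mean zero), then rescaled so the factors' geometric mean
is exactly 1. One exact consequence worth stating: multiplying one
sample's raw counts by *c* multiplies its size factor *relative to the
other samples* by *c*, but because the per-gene geometric-mean reference
includes the scaled sample, the factor itself picks up `c^((m−1)/m)` for
*m* samples and every normalized value shifts by the harmless global
constant `c^(1/m)`. The tests assert this exact form rather than the
looser folklore statement.

Abundance summaries report, per receptor: the mean normalized count across
replicates, its SEM (n−1 standard deviation over √n), and the percent of
total OR expression — computed per replicate as `100 · value / Σ_OR value`
and then averaged, so each individual contributes its own percentage and
per-replicate percentages sum to 100. A receptor is *expressed* when it
reaches ≥ 1.0 normalized counts in at least one replicate (both threshold
and replicate count are parameters; the ortholog filter uses the same flag
with three replicates). The *top decile* is everything strictly above the
linear-interpolation 90th percentile of mean normalized expression over
the species' full OR catalog — pseudogenes and truncated genes included,
since abundance distributions are computed over the whole repertoire; an
intact-only mode is available by passing a restricted table. With all
values tied, nothing is strictly above the percentile and the set is
empty. `log10(x + 1)` is a display transform only, except where an
operation explicitly states it (the Welch test below).

## Cross-species comparison (`cross_species`)

**Ortholog filter.** A group is retained when it (i) has exactly one gene
per species, (ii) shares ≥ 40% amino-acid identity with the human
ortholog, and (iii) is expressed. The expression condition does not name a
species scope in the source procedure; here a group passes when its member
gene is expressed (≥ 1.0 normalized counts in ≥ 3 replicates) in at least
one species.

**PCA.** Columns are standardized (n−1 variance) and the correlation
matrix eigendecomposed. Variance explained is reported in percent and sums
to 100; eigenvalues sum to the number of variables; each loading vector's
largest-magnitude entry is made positive, pinning component signs.
Zero-variance variables raise an error naming the variable — silently
dropping inputs is the caller's decision.

**OGG assembly.** Complete groups whose members are all annotated intact
become OGGs, prefixed `OGG1-` (class I) or `OGG2-` (class II); the class
must agree across species, and a gene appearing in two OGGs is an error.
Each OGG's per-species percent-of-total-OR expression is row-standardized
(population SD) to the relative-abundance scale used for clustering
heatmaps (roughly −2 … +2 for six species).

**Clustering and validation.** Ward's minimum-variance method on Euclidean
distances, in the ward.D2 convention (Lance–Williams on squared distances,
square-rooted heights) as implemented by `scipy.cluster.hierarchy.linkage
(method="ward")`. Three internal statistics validate a cut:

- average silhouette width, `s(i) = (b−a)/max(a,b)`, with `s = 0` for
  singletons and when `a = b = 0` (both conventions made explicit because
  the standard definition is silent on degenerate cases);
- Pearson gamma: correlation between pairwise dissimilarities and the 0/1
  different-cluster indicator over unordered pairs;
- within/between ratio: mean within-cluster over mean between-cluster
  pairwise dissimilarity (scale-invariant; smaller is better).

The cluster count is chosen over k = 2..8 by ranking the k values on each
statistic (silhouette and gamma descending, wb ascending) and taking the
best mean rank, ties to the smaller k. The source procedure "balanced" the
statistics without an explicit rule; the mean-rank rule is a reproducible
stand-in. Per-cluster, per-species binomial tests then ask whether a
cluster holds more top-decile members than the 10% baseline.

## Enrichment statistics (`ligand_enrichment`)

The two-tailed exact binomial test uses the method of small p-values:
`Σ P(X = j | n, p0)` over all `j` with `P(X = j) ≤ P(X = k)·(1 + 1e−7)`,
capped at 1. The relative tolerance absorbs floating-point noise in pmf
comparisons; this is the dominant convention for two-sided exact tests and
reproduces the reference scenario `binom_two_tail(13, 89, 0.10) = 0.1552`.
The baseline p₀ = 0.10 is fixed by the definition of the top decile, never
estimated from data.

The Wilson score interval is used for proportions (exact collapse to 0 at
k = 0 and 1 at k = n). Welch's t uses the Welch–Satterthwaite degrees of
freedom; two constant samples with equal means give t = 0, p = 1 by
convention. A receptor is *deorphaned* when it has ≥ 1 ligand pair, and
class-positive when ≥ 1 pair carries the class flag; `other` means at
least one pair that is neither KFO nor SMC. The enrichment report compares
class receptors against deorphaned non-class receptors: fold change on
untransformed means, Welch's t on `log10(x + 1)` means by default (mean
normalized counts are approximately log-normal, making the t-test
assumptions reasonable on the log scale; a `linear` mode exists). A class
with no testable receptors returns a typed `NoTestResult` rather than a
degenerate statistic.

## Odor space (`odorspace`)

Descriptor filtering drops a column when, checked in this order: (c) any
value is missing; (a) the modal value's frequency exceeds 0.9; (b) the
modal count exceeds 19× the second-modal count (count vs count, strict
`>`; with a single distinct value rule (a) fires first). Order and tie
semantics are pinned here because the thresholds alone do not determine
them; the removal log records the first rule that fired, and the filter is
idempotent. Note the interlock at the thresholds: 95-of-100 identical is
removed by rule (a) (0.95 > 0.9) but not by rule (b) (95 > 19·5 = 95 is
false).

Odor-space projection fits the correlation PCA on the full reduced matrix
and only flags the highlighted subset, so highlighted molecules are placed
in the context of the complete compound set. Sensory profiles are
per-category fractions of an odorant set (multi-label odorants count once
per category; the vector need not sum to 1), compared with Spearman's rho
using mid-ranks for ties and the two-sided t approximation for the
p-value (adequate at the small category counts involved; an exact
permutation option is deliberately not the default). The default category
vocabulary ships as a plain-text file and is replaceable.

## Synthetic data (`synthetic_data`)

The generators emulate the statistical structure the analysis assumes, not
raw sequencing: no reads, no alignment, no sequence evolution.

- **Catalogs**: per-gene status (intact / pseudogene / truncated) and
  class (I / II) drawn with configurable fractions (defaults 0.65 / 0.30 /
  0.05 and 20% class I — repertoires where intact and class II genes
  dominate).
- **Counts**: gene mean abundances are log-normal, `ln mean ~ N(4.0,
  1.8²)` by default — a heavy tail in which the top decile of genes
  carries well over half of all OR counts, matching the "few dominant
  subtypes" regime. Disrupted genes are scaled by 0.1 (the direction,
  lower pseudogene expression, is established; the magnitude is a modeling
  choice). Counts are negative-binomial with dispersion r = 25 (variance
  `m + m²/25`, ~20% biological CV — consistent with the very high
  inter-replicate rank correlations reported for this tissue; `r → ∞`
  recovers Poisson), multiplied by per-sample size factors drawn uniformly
  from [0.5, 2]. Counts are always integer NB draws, never rounded
  Gaussians, so normalization semantics stay honest.
- **Ligand annotations**: disjoint ligand classes claim configurable
  fractions of the intact repertoire; receptors of the planted class
  (default KFO) have their true mean abundance multiplied by
  `planted_fold` (default 2.4) *before* count generation.
- **Orthology**: 73 planted complete 1:1 intact groups (18 class I, 55
  class II) plus distractors — groups missing a species, groups below 40%
  identity (which also carry a pseudogene member so the intact-only OGG
  assembly excludes them independently of the identity filter), and
  groups with a pseudogene member. Distractor counts shrink automatically
  when catalogs are small.
- **Descriptors**: planted exactly-constant, near-constant (modal
  frequency > 0.9), mode-ratio (> 19× while frequency ≤ 0.9), and
  missing-value columns among clean continuous ones, with removal-truth
  labels.
- **Annotation fixture**: one toy chromosome whose hits exercise every
  merge rule, with the expected inventory constructed alongside; the
  identity-tie winner is fixed by replaying the tie in isolation with the
  run seed.

Every generator draws from a named substream of the single global seed
(`SeedSequence` spawn keys from a CRC of the stream name), so adding a
generator never perturbs another's draws and equal seed + config gives
bit-identical output. Replicate counts default to three per species and
are configurable per species.

What passing tests on this data do **not** show: robustness to mappability
artifacts, 3′ bias, GC effects, batch structure, cross-individual OR
genotype variation, or mis-specified orthology — none of which the
generators model. Recovery results certify the estimators under the
generative assumptions (log-normal abundance, NB noise, multiplicative
depth), not under every failure mode of real libraries.

## Problem sizes and numerical choices

Default synthetic repertoires use 400 ORs per species with 3 replicates —
the scale of a human OR catalog and of the profiled study design — and 73
planted OGGs; size-factor recovery checks use 2000 genes × 4 samples
(recovery within 2% relative error after geometric-mean rescaling);
cluster-count recovery uses 100 seeded 72-object blob matrices; enrichment
power and calibration use 200 and 400 replicates of 730-receptor
scenarios. Stochastic tests are seeded and therefore reproducible;
acceptance-style checks run in minutes on a single core.

Tie-breaks and degenerate inputs are handled explicitly throughout:
identity ties by seeded choice, rank ties in cluster-count selection by
the smaller k, percentile ties by the strictly-above rule, silhouette
degeneracies by the s = 0 conventions, constant vectors and zero-variance
columns by typed errors rather than NaN propagation.

## Known limitations

- The expression scope of the ortholog filter (condition iii) and the
  per-species three-cluster re-examination are underdetermined by the
  source procedure; the choices here are documented above and in the
  ortholog-filter docstring.
- `enrichment_report` treats receptors as exchangeable under the null;
  when the top-decile set is defined on the same data (as in the
  calibration tests) the effective null is hypergeometric, making the
  binomial test slightly conservative.
- The pipeline's annotate stage demonstrates the merge on the packaged
  fixture; on real data the stage consumes user-supplied hit tables and
  GTFs through the same functions.
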