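# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `scdyn`.

## Preprocessing

Cells pass QC only if all five thresholds hold: at least 50,000 counts
from endogenous (non-mitochondrial) genes, at least 5,000 genes
detected, less than 90% of counts in the 100 highest-expressed genes,
less than 15% mitochondrial counts, and a mapping rate of at least
60%. These defaults describe a genome-wide experiment;
`QcThresholds.synthetic_defaults()` rescales them for the desk-scale
synthetic gene universe (a few hundred genes), where the genes-detected
and top-100 criteria lose their meaning — with 200 genes the top 100
hold essentially all counts, so a top-100 threshold of 1.0 is treated
as "criterion disabled".

Normalisation is log2(CPM+1) with library-size size factors. The
original analysis this package re-implements used pooled-deconvolution
size factors; library size is an approximation that keeps every
downstream statistic on the same log2(CPM+1) scale, and
`normalize_log_cpm` accepts user-supplied size factors for callers who
want deconvolution-based ones.

The expressed-gene filter keeps a gene if, in at least one experiment
("batch"), (i) its raw count exceeds 100 in some pre-QC cell and
(ii) its mean log2(CPM+1) over post-QC cells exceeds 1. Union-across-
batches semantics were chosen because a gene robustly expressed in any
batch carries usable signal; intersection would discard genes silent
in a single failed experiment.

Highly variable genes: per-gene variances are computed on residuals
after removing experiment means (a design-matrix batch correction),
a lowess trend of variance on mean (span 0.3) is made monotone
non-decreasing by isotonic regression, and the ratio of observed to
trend variance is referred to a scaled chi-square with the residual
degrees of freedom, BH-corrected at FDR 1%. The monotone trend is a
deliberate simplification of package-internal spline machinery used in
the original; its inaccuracy at the high-mean end is conservative
(variance there is over-estimated, not under-estimated).

## Pseudotime, stages, windows

Pseudotime is PC1 of the top 500 highly variable genes
(gene-standardised), sign-oriented to correlate positively (Spearman)
with the numeric collection day, then linearly rescaled so the
observed minimum is 0 and the maximum 1. The sign convention is ours;
principal components are sign-ambiguous and the day of collection is
the only external arrow of time available.

Stage rule (a pure function of day and pseudotime): all day0 cells
are iPSC; day1/day2 cells with pseudotime in the closed interval
[0.15, 0.5] are mesendoderm; day2/day3 cells with pseudotime strictly
above 0.7 are definitive endoderm; everything else is unassigned.
Boundary inclusivity (closed at 0.15 and 0.5, open at 0.7) is our
reading of "between 0.15 and 0.5" and "higher than 0.7".

Sliding windows hold `round(frac*N)` cells (default 25%) and start at
ranks `round(i*step*N)` (default 2.5%), ties in the pseudotime sort
broken by cell id for reproducibility. When N is a multiple of 40 this
yields exactly 31 windows with exact strides. For other N two guards
keep the union of windows gap-free: a start is clamped to the previous
window's end if rounding would skip a rank, and a final boundary
window at `N - width` is appended if the last regular window stops
short of the end.

## cis-eQTL mapping

Pseudo-bulk rows are unweighted means of log2(CPM+1) over
(donor, stage-or-day, experiment) groups; a donor differentiated in
two experiments contributes two rows. Kinship is realised relatedness
`K = ZZ'/m` on per-variant standardised dosages (monomorphic variants
skipped), expanded to analysis rows by donor, so duplicated donors form
unit-correlation blocks — this is what lets the mixed model treat
repeated pseudo-bulk rows of one donor as replicates rather than
independent samples.

Per gene, the null model (intercept + 10 expression PCs) is fitted by
maximum likelihood over the variance ratio h² in
V = h²K + (1−h²)I on the eigenbasis of K (grid of 21 values plus
bounded refinement; the profile likelihood is well-behaved in one
dimension). The fitted ratio is reused for every cis variant of the
gene, reducing each variant test to weighted least squares in the
whitened space — the standard score/EMMAX-style approximation. At the
boundary h² = 0 the procedure is exactly OLS, which the tests verify
to 1e-8. Phenotypes and dosages are standardised, so β is in phenotype
standard deviations per standardised allele. Lead variants are the
minimum p per gene, ties broken by distance to gene start, then
position.

Permutation adjustment permutes donor labels of the genotypes
(expression, covariates and kinship fixed), takes the per-permutation
minimum p across the gene's cis variants, and reports the empirical
tail with a +1 pseudocount, so the smallest attainable value is
1/(n_perm+1). Storey q-values estimate π₀ on a λ grid (0.05–0.95 by
0.05) with a cubic smoother evaluated at the largest λ, clipped to
(0, 1]; forcing π₀ = 1 reproduces Benjamini–Hochberg exactly.

Stage sharing calls a lead effect replicated in another stratum when
the same variant is nominally significant (p < 0.05) there with a
consistent direction. Lead switches require distinct lead variants in
distinct strata, each significant at FDR 10%, with pairwise LD
r² < 0.2 (squared Pearson correlation of dosages).

Note on covariates at desk scale: with a 200-gene panel in which half
the genes carry injected cis effects, expression PCs partially absorb
the genetic signal itself (each eQTL is a visible fraction of total
variance, unlike in a genome-wide panel) and attenuate β̂ by ~15–20%.
The effect-size recovery tests therefore use explicit day and
experiment indicator covariates instead of PCs; the pipeline default
remains 10 PCs, which is the right choice at genome scale.

## Allele-specific expression

Per (cell, SNP) allelic counts are converted to chrB-allele reads
using each donor's phase (`chrA|chrB`, 0 = reference): for phase
`1|0`, chrB reads = total − alt reads; for `0|1`, chrB reads = alt
reads. Records at homozygous or unphased sites, or with zero reads,
are rejected with a reason. Gene-level counts sum chrB and total reads
over the gene's exonic SNPs in that cell; a SNP overlapping several
genes counts toward each. Orientation to the eQTL variant maps chrB
reads to "reads from the chromosome carrying the eQTL alternative
allele" (identity for phase `0|1`, complement for `1|0`); donors not
heterozygous at the eQTL variant are dropped. The allelic fraction is
alt-chromosome reads over total. The composition of these three steps
is tested for exact equality against an independent single-pass
implementation, and for invariance under flipping every recorded
phase (which swaps chrA/chrB labels but not the biology).

Pseudotime bins reuse the sliding windows over all cells; each
(eQTL, window) summary uses the member cells that carry a record for
that eQTL (equal cell counts per window, unequal record counts), with
SEM = sd/√n undefined at n = 1. Allele-resolved expression multiplies
the window's mean ASE (± SEM) by the mean CPM of the gene over
heterozygous cells in the window, so the two alleles always sum to the
mean expression.

## Interaction tests

The three families are ordinary least squares on per-cell allelic
fractions — unweighted, since the underlying framework is linear
modelling of ASE, not count models — compared by Gaussian LRTs with
profiled residual variance: dynamic (pseudo + pseudo² vs intercept,
2 df), cellular factor (adds the factor, 1 df; pseudotime covariates
always included so factor effects are not pseudotime effects in
disguise), higher-order (adds pseudo×factor, 1 df). Only eQTL with at
least 50 records are tested. BH runs within each family separately;
families are never pooled. Besides the tested coefficient, the dynamic
family reports a marginal slope b₁ + 2·b₂·mean(pt) — the average
d(ASE)/d(pseudotime) over the observed cells — because the raw linear
coefficient is strongly collinear with the quadratic term and is not
by itself an interpretable slope.

The chi-square reference makes the n = 100 LRT mildly anticonservative
(≈ 5.5–6.5% rejection at nominal 5%), which the calibration tests
bound within [3%, 7%].

Window profiles of expression and ASE are z-scored per row, stacked,
and clustered jointly by spectral clustering (k = 4 by default) with
affinity (1 + r)/2 from the Pearson correlation between profiles —
a non-negative monotone transform of the negative-correlation
dissimilarity — with a seeded k-means assignment step.

## Co-expression modules and factors

Modules come from affinity propagation on the gene-gene Pearson
correlation over all cells, on the top 8,000 genes by mean expression
(or all genes when fewer exist). The preference defaults to the median
off-diagonal similarity. Damping is 0.7: at desk scale, heavier
damping (0.9) slows the message passing enough that scikit-learn's
stability-based convergence criterion fires before block structure is
resolved, merging clearly separated modules. A module's per-cell score
is the z-score (across cells) of the mean of per-gene z-scored member
expression — "normalised mean expression" made precise — so every
factor enters the interaction tests with mean 0 and unit variance.
Factor labelling is delegated to `term_enrichment` (one-sided Fisher
exact tests against a user-supplied gene–term table, BH at FDR 10%);
the package bundles no ontology. The pipeline, which has no annotation
table, takes the four largest modules as factors.

## Differentiation efficiency

Efficiency of a (donor, experiment) pair is the mean pseudotime of its
day-3 cells; pairs with fewer than 10 cells are dropped. Markers are
tested in a crossed random-intercepts model (experiment and donor) fit
by maximum likelihood through the Woodbury identity (cost linear in
observations), with 1-df LRTs and BH across markers; genetic markers
are restricted to lead variants of eGenes, coded as 0/1/2 dosage. Sex
enters the same model as a fixed effect, coded deterministically by
sorted category label so relabelling flips the sign. Replication
against independent measurements is simple linear regression with
"replicated" meaning nominal p < 0.05 and a consistent direction.
Chromosome enrichment of significant markers is a one-sided Fisher
exact test with fold = (hits on chrom / hits) / (universe on chrom /
universe). ML LRTs for donor-level covariates are anticonservative
when donor levels are few; at the 50-donor scale used in the tests the
null rejection rate is ≈ 5–6% at nominal 5%.

## The synthetic-data generator

The generator emulates, per `SimulationConfig` (defaults in
parentheses): donors (30) pooled `lines_per_pool` (5) per experiment
(6), four collection days with `cells_per_donor_day` (50) cells each,
genes (200) spaced 1 Mb apart on one chromosome so cis windows are
disjoint, 5 cis SNPs per gene plus 2 exonic SNPs, allele frequencies
uniform in (0.1, 0.5), and ~100,000 counts per cell so pseudo-bulk and
allelic depths are realistic.

Latent structure: pseudotime is Beta-distributed per day with means
increasing (0.125 → 0.875, concentration 8) — the observed PC1–day
association prescribes no generative law, so a smooth day-coupled Beta
is the simplest choice producing overlapping day distributions.
Per-line differentiation rates shift the day-specific Beta mean on the
logit scale (sd 0.4), producing the large line-to-line variation in
day-3 progress that the efficiency analysis targets. Two latent
N(0, 1) cellular factors each drive a 20-gene module and modulate
allelic ratios of GxE eQTL. Expression means on the log2 scale sum a
baseline (uniform 3–8), a trajectory term (60 genes, coefficients
±U(1, 2)), donor effects (sd 0.3), experiment effects (sd 0.2), the
cis term (β_static + β_dynamic·pt)·dosage with β = 0.5 on half the
genes (30% of those dynamic, 30% GxE), and residual noise (sd 0.5);
relative weights 2^mean become negative-binomial counts
(dispersion 0.1). Five mitochondrial genes and 2% low-quality cells
(low totals, inflated MT fraction, poor mapping rate) give QC
something to do. Donor sex is assigned at random.

Allelic counts: a gene's count in a cell is split uniformly (rounded
share) across the donor's heterozygous exonic SNPs — the simplest
model that still exercises SNP-to-gene aggregation — and each share is
split between haplotypes by a beta-binomial (concentration 50) whose
mean is logistic in ln(2)·(β_static + β_dynamic·pt) + γ·factor on the
haplotype carrying the eQTL alternative allele. The ln(2) factor makes
the expression-scale and allelic-scale effect sizes consistent: a
log2 effect β on one allele implies a mean fraction
2^β/(1 + 2^β) = logistic(β ln 2). Haplotype phase is exact in the
truth — no phasing-error model, since phasing quality is upstream of
this package's scope.

What the generator does not emulate: doublets, ambient RNA,
demultiplexing error, read-level artefacts (mapping bias, reference
bias), phasing errors, LD between variants (all variants are drawn
independently, so lead-switch analyses see an idealised LD structure),
and genotype–efficiency coupling (line rates are independent of
genotype, making the pipeline's efficiency-marker scan a true null).
Passing tests on this generator demonstrate correct arithmetic,
calibration and parameter recovery under the stated model — not
robustness to those real-data artefacts.

Determinism: every stage draws from `numpy.random.SeedSequence([seed,
stage_index])`, so outputs are bit-identical under a fixed seed and
each stage is reproducible in isolation.

## Problem sizes used in tests

The test-suite simulations are sized for quick, well-powered checks:
the shared fixture uses 30 donors × 60 genes × 25 cells/donor/day;
calibration tests use 400–1000 replicates; the end-to-end check runs
the full default configuration (30 donors, 200 genes, 6000 cells)
twice to verify bit-reproducibility. Effect-size recovery pools three
default-scale simulations (≈ 210 injected effects).

## Known limitations

- Library-size normalisation ignores composition effects that pooled
  deconvolution corrects.
- The per-gene variance-ratio reuse (EMMAX approximation) slightly
  misstates p for variants with large effects; an exact per-variant
  refit is not currently exposed.
- Gaussian LRTs on allelic fractions ignore read-depth
  heteroscedasticity; depth-weighted or beta-binomial regression would
  gain power at low coverage.
- Storey's π₀ smoother uses a cubic spline evaluated at the largest λ;
  on very small p-vectors π₀ is noisy (it is clipped to
  [1/n, 1]).
- The ML mixed-model LRT for donor-level markers is anticonservative
  below ~20 donor levels.
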