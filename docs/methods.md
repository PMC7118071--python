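# Methods

## Scores

The raw PS of haplotype *h* is Σ β<sub>i</sub> x<sub>ih</sub> over scored
variants, with x the count of the weight table's effect allele; the
mean form divides by the number of observed variants. All standardized
quantities use the mean form — for a fixed variant set the sum and mean
forms give identical z-scores, and the mean form stays well defined when
subsets or missing calls change the denominator. Missing genotypes are
excluded from both numerator and denominator (score = mean over observed
sites) rather than imputed; the count N_S reported per individual is the
number of observed allele copies actually scored.

A partial PS restricts the mean to a genomic subset and is standardized
against the mean/sd (sd with n−1 denominator) of the identically
subset-restricted statistic over a reference population. Haplotypes are
scored independently and merged as the SNP-count-weighted mean of their
raw values, which equals a direct mean over both haplotypes' subset
sites; standardization happens after the merge. When each admixed
individual carries its own local-ancestry mask, the reference moments are
computed by transplanting that individual's haplotype mask *pair* onto
the reference panel (haplotype 1's subset applied to each reference
individual's first haplotype, and so on). A shared-mask fast path
computes the reference moments once for experiments that apply a single
subset to a whole cohort.

The ancestry fraction p of an individual is the mean over its two
haplotypes of the fraction of scored SNPs labeled with that ancestry
(unknown-labeled sites count in the denominator). aspPS computed from
p < 0.10 of the genome are marked absent and excluded from population
analyses and from the casPS combination; the threshold is strict
(p = 0.10 is retained).

casPS = Σ p̃<sub>a</sub>·aspPS<sub>a</sub> over ancestries with a present
aspPS, with fractions renormalized over those ancestries; it is emitted
only when at least two ancestry-matched weight sets are available and is
not re-standardized after combination.

**√p bias law.** For iid sites with a constant raw-score mean shift, the
shift of the *standardized* pPS scales as √p: the raw shift is
p-independent while the reference sd scales as 1/√N_S. Dividing by √p
removes the p-dependence of the mean at the cost of inflating the sd by
1/√p. The correction is available (`correct_sqrt_p`) but off by default:
inflated-variance corrected scores degrade trait prediction, so the
uncorrected aspPS is the default throughout.

## Masks

Dosages are hard-called to the argmax ancestry when it reaches the 0.9
threshold, otherwise unknown; exact argmax ties are unknown
(conservative). Masks are defined on the harmonized SNP set that enters
the score, not on all genomic SNPs. The deranged-mask null reassigns
observed mask *pairs* (both haplotypes of an individual move together)
via rejection sampling from uniform permutations, which is exactly
uniform over derangements with acceptance ≈ 1/e.

## Harmonization

Weight tables and genotypes are intersected on (chrom, pos); effect/other
vs ref/alt orientation is resolved by swapping (x → 1 − x), and
non-matching allele pairs are dropped. Strand flips are not attempted —
palindromic (A/T, C/G) SNPs are removed at load precisely so that strand
ambiguity cannot silently corrupt orientation, and the MAF < 0.01 filter
applies when a frequency column is present. With several weight tables,
states are kept ALT-oriented and each table's β is sign-flipped instead;
standardized scores are invariant to this choice. Weights are consumed
pre-clumped; no LD processing is performed.

## Population statistics

True aspPS are compared with deranged-mask aspPS of the same individuals
by a one-sided Wilcoxon signed-rank test on magnitudes
(d = |true| − |null|): toward 0 for the GWAS's own ancestry, away from 0
otherwise. Zero differences are dropped and ties get average ranks. For
n ≤ 25 the p-value is exact — the null distribution of W⁺ is built by
convolution over the (doubled, hence integer) rank values, identical to
enumerating all 2ⁿ sign assignments; above that a continuity-corrected
normal approximation with tie-adjusted variance is used.

PS bias is mean standardized PS minus mean standardized trait, both
z-scored against the reference population. F_ST is the Weir–Cockerham
(1984) estimator in its two-level form (variance components a, b, c with
observed heterozygosity), with the weighted average Σa / Σ(a+b+c) over
sites and negative per-site components retained in the sums; sites
monomorphic everywhere are skipped. Significance stars are raw
(\* ≤ 0.05, \*\* ≤ 0.005, \*\*\* ≤ 1e−5), with no multiple-testing
correction, and are labeled as such.

## Predictivity

The base model is a GLM of the trait on non-genetic covariates (the
standard set being sex, age polynomials, batch and the ancestry SNP
fraction; configurable). Each extended model adds one PS configuration.
Predictivity is realized R² on a prediction set: for linear models
1 − SS_res/SS_tot under the transported coefficients; for binary traits
the Nagelkerke R², with the null log-likelihood taken from the
evaluation set's own prevalence. Added R² is realized minus base R².
Its standard deviation comes from bootstrap resampling of
prediction-set individuals with coefficients held fixed (5000 replicates
by default); a refit-per-replicate mode exists for sensitivity analysis.
Nested models are compared by a χ² likelihood-ratio test, non-nested
ones by the classical Vuong test (z = √n · mean(m)/sd(m) on pointwise
log-likelihood differences) without AIC/BIC adjustment or the
preliminary variance test. Balanced fitting sets downsample every group
to the smallest group's size. Rank-deficient designs are rejected with
the collinear columns named.

## Synthetic data

**Transferability model.** Trait y ~ N(0,1). The A-ancestry score
component correlates r_A with y and is unbiased; the B component
correlates t·r_A (transferability t ∈ [0,1]) and carries a mean shift b.
The observed total PS is p·A + (1−p)·B with p the individual's
A-ancestry proportion; a second, B-calibrated score provides an unbiased
aspPS_B with correlation r_B (default r_A). Defaults: n = 2000,
r_A = 0.5 (a strongly predictive PS, R² = 0.25), t = 0.5, b = 1,
p ~ Beta(6,6). Scenarios described as "p = 0.5" use a Beta distribution
with mean 0.5 rather than a constant, because the PS+p regression model
is rank-deficient under constant p; grid evaluations shift the Beta mean.

**Cohort simulator.** Ancestral allele frequencies are drawn uniformly
in (0.05, 0.95) and the two populations diverge under Balding–Nichols
drift F (Beta(q(1−F)/F, (1−q)(1−F)/F), clipped to [0.01, 0.99]); the
measured F_ST between the derived panels ≈ F for small F. Each haplotype
receives ancestry tracts from a Poisson switch process with g events per
Morgan over an L-Morgan map (defaults g = 10, L = 35, the genome-wide
map length); a tract is an inter-switch segment whose ancestry is drawn
iid from the individual's admixture proportion, so the mean tract length
is exactly 1/g Morgans (merged same-ancestry runs are longer). True
per-SNP effects are bivariate normal across ancestries with correlation
ρ (default 0.6); each allele copy is weighted by the effect of its own
local ancestry; Gaussian noise sets the heritability (default h² = 0.5),
and binary traits use a liability threshold at the configured
prevalence. GWAS weight tables are the true effects plus Gaussian noise
with the standard per-SNP standard error sd(y)/√(2·n·f(1−f)), so an
"effective GWAS n" knob (defaults 100,000 vs 20,000) reproduces the
power gap between a large and a small discovery biobank.
`degrade_dosages` converts true masks into noisy posteriors (top label
dosage 1 − softness; a fraction of sites displaying a wrong label) for
sensitivity studies of the hard-call threshold.

What the generator does **not** emulate: linkage disequilibrium within
ancestries (sites are exchangeable given ancestry), selection,
assortative mating, genotyping error, relatedness structure, or more
than two ancestral sources in the tuned scenarios. Passing tests
therefore demonstrate the statistical machinery under the stated model,
not robustness to every property of real biobank data.

## Numerical choices

Allelic states are int8 with −1 as the missing sentinel. Per-individual
reference standardization of a whole cohort is a chunked dense
matrix product; the cohort-scale experiment driver uses float32
accumulation there (observed agreement with float64 ≈ 3e−6 on z-scores,
far below any tolerance used), while the default and all small-scale
paths are float64. Reference panels must be complete for the batched
path; the scalar path handles missing reference calls. Degenerate
references (σ = 0) raise in the scalar API and are flagged per
individual in cohort scoring. Experiment problem sizes (e.g. 20
replicates of n = 4000 × 20k SNPs for the admixed predictivity
comparison; reference panels of 150–200) were chosen to give stable
Monte-Carlo estimates on a single CPU.

## Known limitations

* The Vuong implementation is the classical unadjusted test; packages
  differ in defaults (variance pretest, AIC correction), so z-values are
  comparable only to the classical form.
* The bootstrap keeps coefficients fixed (prediction-set resampling
  only) by design; refitting gives wider sds.
* Tract simulation is Markovian with exchangeable proportions — real
  admixture histories produce length distributions with heavier tails.
* K > 2 ancestries are supported by masks, scoring and casPS, but the
  cohort simulator's tuned scenarios are two-way.
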