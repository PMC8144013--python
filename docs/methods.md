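# Methods

This note records the statistical models, conventions and design choices
behind `cdgps`, and what the synthetic-data generator does and does not
emulate.

## Data model and conventions

Genotypes are effect-allele dose counts in {0, 1, 2} with NaN as the
missing sentinel. Positions are 1-based; genomic windows are closed
intervals in basepairs. Three dialects are read and written losslessly
(PLINK text .ped/.map, TSV dosage with a `.variants.tsv` sidecar, VCF with
GT only). No strand inference is attempted: an effect allele matching
neither recorded allele is a hard error listing the offending variants,
because the intended use is a fixed, curated SNP panel, not genome-wide
harmonisation.

**X chromosome.** Hemizygous males are coded 0/2 on the allele-count scale
but contribute a *single* allele wherever alleles are counted: MAF uses
allele weights (½ dose, 1 allele for males), allele tables accumulate per
sex, Hardy–Weinberg is evaluated in females only, and association tests on
X are stratified by sex and combined by Mantel–Haenszel (CMH χ², MH pooled
OR with the Robins–Breslow–Greenland interval via statsmodels). Pooled
male+female X allele tests are deliberately not available.

## QC

Filters with their defaults: missingness ≥ 5 % drops; absolute
case/control missingness difference ≥ 3 % drops; MAF ≤ 1 % drops; exact
HWE *P* ≤ 10⁻⁶ in controls drops. Boundaries are strict as stated (4.99 %
missingness passes, 5.0 % fails). The differential-missingness rule is an
absolute difference, not a test, which is the simplest reading of a
percentage cutoff. The HWE test is the exact conditional test (probability
of the heterozygote count given allele counts, two-sided by summing
configurations no more probable than observed). The implementation seeds
the recurrence at the modal heterozygote count so probabilities only
shrink outward — numerically safe at thousands of samples — and is
verified against full enumeration in rational arithmetic for small tables.
Monomorphic variants return *P* = 1 by convention. Filtering is
idempotent.

## Association

The primary statistic is the Pearson χ² (1 df, no continuity correction)
on the 2×2 allele-count table of a contrast, which is always
*phenotype-positive cases versus population controls*; contrasts with
fewer than five events are not tested (configurable). The crude OR carries
a Woolf log-scale interval, exp(ln OR ± 1.95996·√(1/a+1/b+1/c+1/d)); a
zero cell triggers the Haldane–Anscombe 0.5 correction on all cells with a
flag. Two published rows rebuilt from printed per-group MAFs
(counts = round(2n·MAF)) reproduce their printed OR and CI to two decimals
— 1.28 (1.12–1.46) for a common variant at n = 573 vs 1817, and 3.19
(1.62–6.28) for a 19-patient subgroup — which pins down both the counting
convention and the CI method.

A sex-adjusted logistic model (logit(label) ~ dose + female, optional
dose×female interaction) is reported *alongside* the crude OR, never
instead of it, since the published estimates are reproduced exactly by the
crude calculation. Separation and non-convergence are flagged on the
result rather than raised.

Breslow–Day homogeneity across sex strata: the expected group-1
effect-allele count under the MH common OR solves the usual quadratic per
stratum; the statistic Σ(aₖ − Ãₖ)²/Var(aₖ) has K−1 df. The Tarone
adjustment is available but off by default; the implementation matches
statsmodels' `test_equal_odds` to 10⁻⁸ on random tables and that library
serves as the independent oracle in tests. The conventional significance
threshold surfaced for this test is 0.02 (0.05/2, one split per sex).

## Permutation empirical P

Labels are shuffled among samples, genotypes fixed; within-stratum
shuffling (e.g. within sex) is available to preserve covariate–genotype
structure. The permuted statistic is the allelic χ² computed from allele
counts, which turns the whole family × permutation computation into two
matrix products (effective-dose and allele-multiplicity matrices against a
permutation indicator matrix) — 10⁴ permutations on a 39-variant,
2 442-sample family take well under a second. EMP1 and EMP2 use the
+1/(R+1) estimator, so no empirical *P* is ever zero and
EMP2 ≥ EMP1 ≥ 1/(R+1) always. The EMP2 family is all QC-passing variants
tested against the given phenotype. A permutation in which a variant's
table has a zero margin contributes statistic 0, with a per-variant tally.
An exhaustive mode enumerates all C(n, k) label assignments for small
cohorts and is checked against brute-force enumeration.

Calibration at the study's design scale (39 variants, 300/900 samples,
999 permutations, 500 replicate null cohorts): the family-wise rate of
any EMP2 ≤ 0.05 lands within two Monte-Carlo standard errors of 0.05, and
EMP1 for a fixed variant across replicates is uniform by
Kolmogorov–Smirnov. Uniformity is assessed on one variant per replicate
because EMP1 values within a replicate share permutations and are not
independent.

## Weighted GRS

score = Σᵥ dᵥβᵥ / (2·n_used), with β = ln OR per risk allele and n_used
the variants non-missing *for that sample* — "total number of alleles" is
read as twice the scored variant count, the per-allele average of the
standard weighted-GRS construction; a sample with no scored variants is an
error rather than a silent zero. Tertile cutpoints are the 33⅓ and 66⅔
linear-interpolation quantiles of the *control* scores only (the method is
recorded in output metadata because tertile boundaries are sensitive to
the quantile convention); assignment is left-closed (low ≤ t₁ < medium ≤
t₂ < high), and cases are always classified against control cutpoints.
Tertile association is a sex-adjusted logistic model with medium and high
indicators against the low reference; fewer than five events in the
reference tertile skips the contrast with a recorded reason.

In recovery simulations (true high-vs-low OR 1.8, 10-variant score,
2 400-sample cohorts, 200 replicates) the high-tertile CI covers the
generative OR in ≥ 95 % of replicates.

## C+T polygenic score

Clumping is greedy: sort by ascending *P* (ties broken by chromosome and
position for determinism), take the best unclaimed variant as index,
remove unclaimed variants within ±250 kb on the same chromosome with
r² > 0.2 against it. r² is the squared Pearson correlation of dose vectors
(composite LD on unphased genotypes), pairwise-complete, defined as 0 with
a warning when a vector is constant. The chromosome-6 long-range-LD region
(29.7–33.3 Mb, coordinates used as printed, no liftover) is excluded
before clumping. The LD reference defaults to the analysis cohort's own
genotypes. Every run's output satisfies, and tests brute-force verify,
the post-condition: retained pairs in a window are quasi-independent and
every removed variant has a retained neighbour with r² > 0.2 and no larger
*P*.

Scores at each threshold are Σ dᵥβᵥ over retained variants with
*P* < threshold (strict). Missing doses are imputed as 2×EAF here — unlike
the wGRS, no per-sample average is taken, so exclusion would make scores
incomparable across samples; the imputed-entry count is reported.

Per-threshold fits are case-only logistic models (flag ~ score + age +
sex); the reported effect size is the Nagelkerke pseudo-R² of the full
model minus the covariate-only model (both against the intercept-only
null), which is non-negative by nesting. "Best fit" is the threshold with
the smallest *P*; its empirical *P* permutes the flag (covariates stay
attached to samples) and repeats the entire minimum-*P* search per
permutation. For tractability at R = 10⁴ the permuted (and observed)
selection statistic is the Rao score test of adding the score to the
covariate-only model — one IRLS fit per permutation instead of one per
threshold — while the fit table reports the full-model Wald *P*; the two
are asymptotically equivalent and the like-for-like comparison keeps the
empirical *P* valid. Null simulations show the best-fit empirical *P*
exceeds 0.05 at roughly the nominal rate while the unadjusted best-fit *P*
is anti-conservative, which is the point of reporting it.

## Synthetic cohorts

The generator's defaults are the study conditions: 625 cases, 1817
controls, 39 variants, the ten published risk variants at their printed
control MAFs with ln(OR) disease effects (the X-linked variant, whose
printed OR covers only a narrow subgroup, carries a substituted modest
protective OR of 0.8), 29 null filler variants across the printed MAF
range, ages uniform on 0.5–79 years, a female disease log-OR of 1.27
(making ~78 % of cases female from a balanced pool), a baseline intercept
of −3 (≈5 % prevalence before enrichment), and sub-phenotype intercepts
set to the published marginal rates among cases, with partial availability
(e.g. mucosal morphology defined for ~546/625).

LD blocks use a one-factor Gaussian copula per haplotype: a shared latent
factor with loading √ρ, alleles thresholded at Φ⁻¹(MAF), genotype = sum of
two independent haplotypes. ρ is calibrated by root-finding on the
bivariate normal orthant probability so the pairwise dose correlation hits
√(target r²); with equal MAFs in a block this is exact, with unequal MAFs
it is approximate through the mean MAF (fixtures use equal MAFs per
block). Realised r² is within ±0.05 of target at n ≥ 2000. Infeasible
targets (unreachable even at ρ = 0.999) raise an error naming the block.

Status assignment is honest rejection sampling: Bernoulli draws from the
logistic liability over a genotype pool (grown ×1.5 until both quotas are
met, bounded attempts), then truncation to exact quotas — so case
genotypes carry the correct case-conditional distribution and a per-allele
logistic fit on the sampled cohort recovers the generative log-OR with
|bias| < 0.05 at 200 replicates (criterion met at OR 2.0, MAF 0.3,
600/1800).

What the generator does *not* emulate: haplotype-phase LD structure
(composite-LD blocks suffice for r²-based clumping but not for
phase-sensitive methods), population structure and relatedness, genotyping
batch effects, informative missingness, and correlation between
sub-phenotype flags (flags are conditionally independent given genotype,
sex and age). Passing tests therefore demonstrate correctness of the
estimators under the assumed model, not robustness to those real-data
complications.

Fixture sizes and replicate counts used in tests and the acceptance script
(500 null replicates × 999 permutations; 200 recovery replicates; 2 400-
sample tertile cohorts; a 1 000-sample LD-demo panel) were chosen so
Monte-Carlo standard errors sit comfortably inside the asserted
tolerances while a full run stays fast on one CPU.

## Numerical details and degenerate inputs

* χ² on a zero-margin table is an error (observed side) or statistic 0
  with a tally (permuted side).
* Exact HWE: tie comparison uses a 1+10⁻¹² relative tolerance so equal
  probabilities on both tails are included, matching enumeration.
* Logistic fits flag separation and non-convergence instead of raising;
  rank-deficient designs return NaN estimates with a flag.
* Degenerate control score distributions (coincident tertile cutpoints)
  warn; the medium class may be empty.
* Quantile method, X-male coding, CI method and the empirical-P estimator
  are written into every run manifest, and all randomness flows from one
  root seed.

## Known limitations

* The published per-row covariate structure (crude vs adjusted) is not
  stated per estimate; both are always reported, and only the two
  reconstructed rows are verified against print.
* Absolute published EMP2 values, the published tertile ORs and the
  published PRS ΔR² cannot be reproduced without the study's
  individual-level genotypes; the corresponding machinery is validated by
  the calibration and recovery properties above instead.
* Placeholder positions are attached to the published variants (printed
  tables give chromosome only); they are spaced beyond one clumping
  window so they never interact.
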