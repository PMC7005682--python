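# Methods

This note documents the statistical models behind `ffapls`, the defaults and
their rationale, what the synthetic-cohort generator does and does not
emulate, and the numerical conventions that matter for reproducibility.

## Genetic layer

**Genotype QC.** Per-SNP criteria are applied as strict inequalities: call
rate > 0.95, minor allele frequency > 0.05, Hardy–Weinberg p > 0.05.
Subjects are then dropped when their missing fraction across the retained
loci exceeds `subject_max_missing` (default 0.0 — with four loci, any
missing call excludes the subject). The exclusion report lists every dropped
SNP and subject with the failed criterion and its value.

**Hardy–Weinberg testing.** The exact test conditions on the observed
minor-allele count and enumerates the conditional distribution of the
heterozygote count; the default mid-p variant counts only half of the
observed configuration's probability, which removes the discrete test's
conservatism. `auto` switches to the 1-df chi-square test when every
expected genotype count is at least 5. Monomorphic loci report p = 1 with a
flag rather than an error.

**EM haplotype estimation.** For each subject the set of haplotype pairs
compatible with the unphased multilocus genotype is enumerated (2^(h−1)
pairs for h heterozygous loci); the EM alternates posterior pair weights
(E-step) with expected haplotype counting (M-step). Initialisation is the
product of allele frequencies (linkage equilibrium); convergence when the
log-likelihood gain drops below 1e-8, capped at 1000 iterations; the
log-likelihood trace is retained and is non-decreasing by construction.
Identical multilocus genotypes are pooled so the E-step scales with the
number of distinct profiles. The estimator is validated against direct
likelihood maximisation over the haplotype simplex (Nelder–Mead from
multiple starts) on small two-locus fixtures, with agreement to 1e-6.

**Linkage disequilibrium.** D is computed from the two-locus EM haplotype
frequencies as p_AB − p_A·p_B and normalised by the standard D_max; |D′| is
reported, which makes it invariant to allele labelling. Monomorphic loci
yield a flagged, undefined result.

**HEA grouping.** Subjects are assigned their maximum-posterior diplotype;
the copy count of the high-enzymatic-activity haplotype G-C-G-G over
(rs6269, rs4633, rs4818, rs4680) maps 2/1/0 to homozygous-HEA /
heterozygous-HEA / non-carrier. Posterior ties are broken by lexicographic
order of the haplotype-pair label and flagged.

## PLS correspondence analysis

The genotype block is coded disjunctively (one indicator column per observed
genotype category; unobserved categories are omitted and logged). Each
column's weight is the inverse of its relative frequency — rare genotypes
carry more information. The default cross-block matrix is the Pearson
correlation matrix between coded columns and z-scored phenotype columns
(n−1 denominator). Pearson correlation is scale-invariant, so the
inverse-frequency weights do not alter this matrix; they are reported and
drive the optional chi-square-metric variant (`metric="ca"`, centred
profiles scaled by 1/√mass), provided for users who want classical
correspondence-analysis geometry.

**Scores and orthogonality.** LV scores are projections of the same
standardized blocks the correlation matrix is built from. With that choice
the cross-block orthogonality x-scoreᵢᵀ·y-scoreⱼ = (n−1)·sᵢ·δᵢⱼ holds
exactly; scores computed from differently scaled matrices would not satisfy
it.

**Sign convention.** The SVD leaves each LV's sign arbitrary. Each LV is
oriented so that the first phenotype salience whose magnitude is at least a
quarter of the LV's largest magnitude is positive. Anchoring on the earliest
participating variable is stable across replicates; anchoring on the
largest-magnitude salience is not, because two saliences of equal population
magnitude (exactly the planted +FS/−fALFF pattern) let sampling noise decide
which is larger, flipping the orientation on roughly half the replicates.

**Permutation test.** Genotype rows are permuted against fixed phenotypes,
preserving the phenotype covariance. The omnibus statistic is total
cross-block inertia (sum of squared singular values); the largest singular
value is reported as an alternative omnibus statistic. Per-LV p-values
compare singular values rank-for-rank with no step-down, which is
anticonservative for later LVs — they are descriptive. p = (#exceedances +
1)/(n_perm + 1), so the smallest achievable p is 1/(n_perm+1).

**Bootstrap.** Subjects are resampled with replacement; resamples that lose
a genotype category (or a phenotype's variance) entirely are redrawn and
counted. Each bootstrap solution is matched to the original LVs greedily on
total salience similarity and sign-aligned before accumulation. BSR =
original salience / bootstrap SE, treated as standard normal for two-tailed
p-values, BH-FDR adjusted within each block and LV; 95% percentile CIs are
also reported. Calibration: at the study scale (n = 338, latent correlation
0.26, n_boot = 500) the CI for a null salience covers zero at 0.96 over 200
replicates. With much smaller resample counts (n_boot = 200) the percentile
method undercovers (~0.92–0.93) — a known property of percentile intervals,
which is why the calibration suite runs at the study's bootstrap count.

## ROI phenotypes

**fALFF** is the ratio of summed one-sided FFT amplitudes in the low band
(default 0.01–0.08 Hz, the resting-state convention; configurable) to the
summed amplitudes over (0, 0.25] Hz, DC excluded. The 0.25 Hz total-band
edge is part of the definition; the sampling interval must give Nyquist ≥
0.25 Hz. A constant series returns NaN rather than raising.

**Standardization** of fALFF maps subtracts the in-mask mean and divides by
the in-mask population SD (divide by N — fixed, documented convention).

**ROI definition** thresholds the group z-map (one-tailed, default z > 2.58)
inside an anatomical mask and partitions suprathreshold voxels into
connected components; 26-connectivity is the default (6/18 selectable).
Whether the ROI is the largest component (default) or the union of all
components is selectable, since either reading is defensible. Components
are ordered by size then seed voxel, making results independent of voxel
visitation order. Voxel indices are 0-based.

**Summaries**: FS = ROI mean contrast z; fALFF = ROI mean standardized
fALFF; GMV = ROI sum of modulated gray matter × voxel volume, optionally
residualized on total brain volume. Split-half reliability partitions ROI
voxels into random equal halves (partition recorded, seed-reproducible).

The package's input boundary is voxel-level z/fALFF/GM maps (or pre-extracted
ROI tables): first-level GLMs, registration and smoothing are upstream.

## Behavior

Accuracy is 100·(hit rate + correct-rejection rate)/2, on the 0–100 scale.
d′ = Z(hit) − Z(FA) with extreme rates replaced by 1/(2N) and 1 − 1/(2N)
(log-linear correction selectable). The default response-bias formula is
c = −Z(hit) + Z(FA), which algebraically equals −d′; the package emits a
one-time warning about this and offers the conventional criterion
c = −[Z(hit) + Z(FA)]/2 via `bias="standard"`. FRA is the residual of face
accuracy on flower accuracy (OLS with intercept), standardized to mean 0,
SD 1 (population SD); old/new scores residualize the hit and
correct-rejection rates on c. Residual scores are exactly orthogonal to
their regressors; a constant regressor raises (FRA) or falls back to
standardized raw rates with a flag (old/new).

## Downstream inference

Partial correlation residualizes both variables on the covariates (with
intercept) and takes the Pearson correlation of residuals; p from the t
distribution with df = n − 2 − k, CI via Fisher z with SE = 1/√(n − k − 3).
Dependent-correlation comparisons use Steiger's Z (pooled-correlation
covariance term); the accompanying effect size is 2z/√n. The haplotype ×
hemisphere ANOVA stacks one row per subject per hemisphere and treats
hemisphere as a crossed factor — hemispheres are actually repeated within
subject, so this replicates the common (slightly anticonservative) stacked
analysis; Type-II sums of squares handle the unbalanced groups, Tukey HSD
uses the Tukey–Kramer correction, post hoc p-values are BH-FDR adjusted,
and partial η² is SS_effect/(SS_effect + SS_error). ICC defaults to the
two-way random-effects, absolute-agreement, single-measure variant
(consistency selectable), with F-based CIs. Observed ("post hoc") power is
deliberately not reproduced: it is a deterministic transform of the p-value
and tool-specific.

## Synthetic cohorts

The generator's defaults are the study conditions: 338 subjects; haplotype
frequencies HEA 0.328 / MEA 0.239 / LEA 0.389 renormalized to sum 1 (the
printed values sum to 0.956 because rare haplotypes are unnamed; an option
assigns the residual 0.044 to a synthetic "other" haplotype, G-C-C-G, a
recombinant chosen by us); planted PLS1 latent correlation 0.258; FRA
coupling 0.138; new-face-score coupling 0.162; 135/338 males; age 20.45
(0.96) years truncated at 17; Raven 25.3 (5.7); face accuracy 76 (9) and
flower accuracy 77.7 (9) percent with 30 old + 30 new trials per category;
inter-hemisphere phenotype correlation 0.79 (the cross-hemisphere ICC scale
reported for latent brain scores).

**Genotypes** are two haplotypes drawn i.i.d. per subject (Hardy–Weinberg
random mating), reduced to unphased genotypes, with optional missingness.

**Phenotypes.** The latent score z is the standardized per-subject sum of
per-genotype-category effects (default: heterozygote +1, homozygotes 0 at
every SNP — an overdominant architecture consistent with the
heterozygote-advantage finding). FS loads +a, fALFF −a, GMV 0 (pattern
configurable), with noise per modality. The loading a is calibrated
*analytically*, not by trial-and-error: the population PLS1 latent
correlation factorizes into the genotype-side attenuation κ — the exact
population correlation between the fitted PLS1 genotype score and z,
computable in closed form from the diplotype distribution (κ ≈ 0.997 under
the defaults) — and the phenotype-side correlation, a monotone function of
a solved by root finding. Targets at or above κ raise an error naming the
bound. Monte-Carlo check: mean fitted latent correlation over 50 replicates
at n = 5000 is within 0.01 of the target.

**Behavior.** Hit and false-alarm probabilities live on probit channels
Φ(μ + τ·(c·z + noise)); μ is inflated by √(1+τ²) so the marginal mean rate
is exact, and τ is set so the total accuracy SD (subject variance plus
delta-method binomial variance at 30+30 trials) matches the configured SD.
The two channel loadings (c₁, c₂) are solved jointly from the FRA and
new-face-score coupling targets under a linearized model of the residual
scores. Monte-Carlo check: recovered couplings within 0.005 of target at
n = 5000. Covariates are generated independently of everything else.

**Voxel maps** place one contiguous blob per hemisphere (6-connected
deterministic region growth, default 233 voxels) inside a box mask; the
group z-map is suprathreshold exactly on the blobs; subject voxel values are
the subject's ROI summary plus i.i.d. voxel noise, and GM voxels spread the
subject's GMV uniformly so the ROI summary round-trips exactly at zero
noise.

**What the generator does not emulate**: BOLD acquisition physics, spatially
structured voxel noise, realistic cortical anatomy or atlases, genotyping
error, population stratification, or any dependence of covariates on
genotype. Passing tests therefore demonstrate the correctness and
calibration of the estimators under the planted model, not robustness to
real-data artifacts.

**Determinism.** Every cohort derives all randomness from one seed through
seed-sequence spawning; identical config + seed give byte-identical
serialized cohorts and pipeline reports.

## Problem sizes in the test suite

The calibration suites use: 500 null datasets of n = 80 with 199
permutations (type-I error); 200 replicates at n = 338 with 500 bootstrap
resamples (CI coverage); 50 replicates at n = 5000 (latent-correlation
recovery); 100 replicates at n = 338 (salience sign pattern); two-locus
n ≤ 20 fixtures for the EM-versus-oracle comparison. These sizes give
binomial/Monte-Carlo error comfortably inside each tolerance band.

## Known limitations

- Unclassifiable diplotypes: cohorts whose diplotype cannot be resolved are
  not specially modelled; every simulated subject receives two named
  haplotypes (real panels report a residual unclassified fraction whose
  defining rule is panel-specific).
- Per-LV permutation p-values are anticonservative beyond LV1 (no
  step-down).
- The stacked hemisphere ANOVA ignores the within-subject correlation of
  hemispheres; a mixed model would be the rigorous alternative and is out of
  scope.
- The EM enumerates compatible haplotype pairs and is intended for ≤ ~10
  loci, not genome-scale phasing.
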