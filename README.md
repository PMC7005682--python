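# ffapls

Imaging-genetics toolkit for multivariate genotype-brain-behavior association,
built around the analysis chain used to relate *COMT* polymorphisms to the
functional profile of the fusiform face area (FFA) and to face-specific
recognition ability:

```
SNP genotypes ──QC──▶ haplotypes / diplotypes (EM)
      │
      └─ disjunctive coding ──▶ PLS correspondence analysis ◀── ROI phenotypes
                                   │  (permutation + bootstrap)   (GMV, fALFF, FS)
                                   ▼
                      latent brain scores ──▶ behavioral associations
                                              (FRA, old/new scores, ANOVA)
```

It is written for biostatisticians and cognitive-neurogenetics researchers who
want a tested, reusable implementation of each stage — and a synthetic-cohort
generator that reproduces the statistical structure of such a study, so every
stage can be exercised without access to raw subject data.

## The model

Each SNP's genotype is coded as three indicator columns (genotypic/codominant
coding), weighted by the inverse of the category's relative frequency; the
three-modal ROI phenotype per subject is z-scored. PLS correspondence analysis
(PLSCA) takes the singular value decomposition of the cross-block correlation
matrix **R** = **X**ᵀ**Y**/(n−1):

  **R** = **U** diag(s) **V**ᵀ

Columns of **U**/**V** are the genotype and phenotype *saliences*; squared
singular values (as fractions of total inertia Σs²) give each latent-variable
(LV) pair's explained cross-block variance; subject scores are the
standardized blocks projected on the singular vectors. Significance comes
from permuting subjects in one block (omnibus statistic: total inertia);
salience reliability from subject-level bootstrap with bootstrap ratios
(BSR = salience / bootstrap SE), percentile CIs and BH-FDR.

Around this core the package provides: Hardy–Weinberg exact (mid-p) and
chi-square tests, genotype/subject QC, EM haplotype-frequency estimation over
unphased multilocus genotypes with diplotype posteriors and D′ linkage
disequilibrium, high-enzymatic-activity (HEA) haplotype dosage grouping,
fALFF computation and ROI definition by threshold + contiguity, old/new
recognition scoring (accuracy, d′, response bias, FRA), partial correlations,
Steiger tests for dependent correlations, two-way ANOVA with Tukey HSD, ICC,
and BH-FDR.

## Worked example

```python
from ffapls import CohortConfig, simulate_cohort
from ffapls.pipeline import RunConfig, run_pipeline

config = RunConfig(simulation=CohortConfig(n_subjects=338, seed=5),
                   n_perm=199, n_boot=200, seed=5)
report = run_pipeline(config)
print(report["haplotypes"]["common_freqs"])
print(report["plsca_right"]["explained_variance"])
print(report["plsca_right"]["y_saliences"])
print(report["behavior_associations"]["fra"])
```

prints (seed 5):

```
{'ACCG': 0.4009, 'ATCA': 0.2382, 'GCGG': 0.3609}
[0.86121, 0.076057, 0.062733]
{'falff': -0.610082, 'fs': 0.79079, 'gmv': 0.049514}
{'r': 0.0579, 'p': 0.290569, 'n': 338, 'ci': [-0.0496, 0.164]}
```

Reading this: the EM recovers the three common haplotypes near their planted
frequencies (0.343/0.250/0.407 after renormalization); the first LV pair
carries 86% of the cross-block inertia with the planted salience pattern —
positive on face selectivity (FS), negative on fALFF, near zero on gray
matter volume; and the face-specific recognition ability (FRA) correlates
weakly and positively with the latent brain score at a single-cohort
magnitude (r ≈ 0.06 here; the planted population coupling is 0.138, and a
cohort of 338 estimates it with SE ≈ 0.054).

The same pipeline is scriptable from the shell:

```bash
ffapls simulate --seed 5 --out cohort/
ffapls haplotypes cohort/genotypes.tsv --out hap/
ffapls run-all --seed 5 --out results/
```

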