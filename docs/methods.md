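# Methods

This note documents the generative model behind the synthetic cohorts, the
estimators, the numerical choices, and what the test suite does and does not
establish about real data.

## Synthetic cohort generator

**Founders and lines.** Each dataset starts from 13 sire/dam pairs of
unrelated founders. Base minor-allele frequencies are drawn per marker
(uniform on (0.05, 0.5] by default). Families are nested within divergent
"commercial lines" (default 7 lines over 13 families, sizes 3,3,2,2,1,1,1 by
round-robin assignment): each line's allele frequencies are drawn from a
Balding–Nichols distribution around the base frequency with divergence
Fst = 0.1. This reflects a cultured cohort assembled from several breeding
lines and is what gives the population a low-dimensional stratification that
three MDS axes can represent; with a single line (`n_lines=1`) the founders
are an unstructured panel and all families are equidistant. Fst = 0.1 is in
the range typical of separately maintained aquaculture strains; it was fixed
once, on the qualitative grounds that the cohort should split into roughly
seven multi-family subpopulations with the largest exceeding 30 animals.

**Linkage disequilibrium.** Founder haplotypes follow a first-order Markov
copula along each chromosome: adjacent markers at genetic distance d
(Morgans) share a latent uniform with probability exp(−d / ld_decay), so
haplotype correlation decays with map distance; `ld_decay = 0.05` Morgans by
default (correlation 1/e at 5 cM), consistent with the long-range LD of a
small-Ne breeding population. `ld_decay = 0` gives linkage equilibrium.

**Map.** 44 chromosomes (shrimp-like karyotype) of 1 Morgan each, markers
evenly spaced — the study organism has no public linkage map, so the map is
deliberately generic.

**Meiosis.** Gametes carry Poisson(L)-many crossovers per chromosome of
length L Morgans, uniformly placed, with a fair-coin starting haplotype;
offspring dosage is the sum of one maternal and one paternal gamete. Each
family contributes 50 offspring; 200 are sampled uniformly without
replacement across the roster (per-family representation in the real cohort
is unknown, so uniform sampling is the neutral choice).

**Traits.** Each trait is additive over `n_qtl = 500` QTL drawn uniformly
among the markers with standard-normal effects ("many small-effect loci");
body weight and body length share 70% of their QTL (with identical effects
on the shared set), inducing a genetic correlation of roughly that size —
the study reports no genetic correlation, so this default is an arbitrary,
documented choice. Given the realized genetic values u, the environmental
variance is set from the *animal-model* additive variance
V_A = var(u)·(n−1)/tr(G) (G the VanRaden matrix of the cohort's markers) as
V_E = V_A(1−h²)/h², so that `target_h2` is exactly the parameter a G-based
REML fit estimates. This matters: under line structure the mean diagonal of
G is ~1.15, so a naive sample-variance calibration would make REML recover
~0.42 when the target is 0.452 — a scale mismatch, not an estimator bias.
The phenotype is affinely mapped to the target mean/SD (weight 5.56/2.16 g,
length 76.99/9.95 mm) and floored at 1% of the target mean so measurements
stay positive (the floor binds for ~1 animal in 200 for weight, shifting the
mean by <0.005 g). Default heritabilities are 0.321 (weight) and 0.452
(length), the study's full-marker estimates.

**Missingness.** Calls are masked independently per (individual, marker) at
a per-marker rate (default 3% everywhere), sized so that the >5%
missing-rate QC filter removes a binomially predictable share of markers.

**What the generator does not emulate.** Sequencing/genotype-calling error,
allele dropout of reduced-representation libraries, haplotype-level founder
pedigrees within lines, selection, multi-generation structure, or
non-additive (dominance/epistatic) variance. Passing tests therefore show
the pipeline's estimators are correct and well calibrated *under an additive
polygenic model with family and line structure* — not that real shrimp data
meet those assumptions.

## Quality control and imputation

Markers with missing rate strictly above 5% or MAF strictly below 0.05 are
removed in a single pass (both statistics from the same input; boundary
markers kept; a float-rounding guard keeps exact-boundary cases such as
10/200 missing). Individuals are never filtered. Remaining missing calls are
imputed by marker mean dosage (or within-family mean with a global-mean
fallback); with ≤5% missingness per retained marker, G matrices and
predictions are insensitive to the imputation method, which is why a
haplotype-phasing imputer is deliberately not used. Imputed dosages may be
fractional; IBS is computed on the pre-imputation integral calls with
pairwise-complete markers.

## REML

The restricted likelihood of y = 1μ + u + e (u ~ N(0, G·V_A)) is profiled
over δ = V_E/V_A using one eigendecomposition of G (eigenvalues clipped at
zero within numerical noise), making each likelihood evaluation O(n).
Optimization is Brent's bounded method on log δ ∈ [−10, 10] (h² constrained
to ~[5e−5, 1−5e−5], i.e. variance components non-negative), convergence
tolerance 1e−8; solutions within 1e−3 of a bound are flagged as boundary
estimates. An independent dense-algebra grid search over h² ∈ {0.00…1.00}
(`reml_h2_grid`) is kept as a reference path and agrees with the optimizer
on every tested instance, including full-scale structured cohorts. On a
13-family/7-line cohort of 200 animals the per-dataset estimate has SD
~0.12, and the estimator retains a small (~−0.02) downward bias at the
length-trait h² — an inherent small-sample property of REML with so few
independent family units, which the real study design shares.

The density curve redraws, for each (density, replicate), a uniform marker
subset from its own spawned random stream, rebuilds G and re-runs REML; a
subset equal to the full panel reproduces the full-panel estimate exactly.

## Prediction models

All models centre dosage columns by training means; predictions are
(X − x̄_train)·g on the deviation scale (the raw 0/1/2 parameterisation
differs only by an intercept, which cannot affect correlations).

- **RR-BLUP**: ĝ = (XcᵀXc + λI)⁻¹Xcᵀ(y − ȳ) with λ = 2Σp(1−p) · V_E/V_A;
  the ratio defaults to REML on the training G. Solved in the dual (n×n)
  form when markers outnumber animals. X·ĝ is identical (to 1e−6 relative)
  to the G-matrix BLUP at the same ratio — the central correctness oracle.
- **BayesA**: Gibbs sampler with σ²ⱼ ~ scaled-inv-χ²(ν=5, S), S set so the
  prior mode of the implied genetic variance equals R²=0.5 of the phenotypic
  variance; residual scaled-inv-χ²(5, S_e) by the same heuristic. Update
  order fixed: μ, g₁…g_m in index order, marker variances, residual.
- **Bayesian LASSO**: normal scale mixture with 1/τ²ⱼ inverse-Gaussian full
  conditionals and λ² ~ Gamma(1.1, rate set so the prior mean matches the
  R²=0.5 heuristic).

Chains run 40,000 iterations with 10,000 burn-in by default (the protocol
used throughout), with a documented fast profile (4,000/1,000) for
desk-scale cross-validation; every sweep is compiled with numba and chains
are bit-reproducible from the config seed. Frozen-variance test hooks reduce
both samplers to (weighted-)ridge posteriors, giving closed-form oracles for
the full conditionals. Posterior means/SDs are accumulated in one pass
(thinning 1); full chains are not stored.

## Stratification and cross-validation designs

Classical (Gower) scaling of D = 1 − IBS: B = −½JD²J, eigendecomposition,
coordinates = top eigenvectors × √eigenvalue; requested axes with
non-positive eigenvalues are zeroed and flagged. k-means (Lloyd +
k-means++, best of 50 starts, seeded) runs on the first three axes; k
defaults to the mean-silhouette maximiser over 2…10, since the study reports
its k without a selection rule. Three near-equidistant axes cannot linearly
separate 13 equidistant families, so subpopulations are unions of complete
families/lines — the same phenomenon as the study's 13 families collapsing
into 7 subpopulations — and cluster recovery is therefore assessed against
line labels (and exactly, on well-separated planted partitions).

Five-fold CV partitions the sample into folds differing by ≤1 in size; each
animal is validated exactly once and accuracy is one pooled correlation per
run, divided by √h²_full (the full-marker REML estimate of that dataset's
trait). Density CV shares each marker subset across models within a
replicate so model comparisons are paired. DIST designs validate on each
subpopulation larger than 30 with the rest as reference; RAND designs are
three seeded stratified 80/20 splits (floor of 0.8·size per subpopulation
into training). Negative accuracies are reported as-is.

## Problem sizes used by the checks

The acceptance-style checks run at the study scale where it matters and at
reduced replication where only Monte-Carlo noise changes: h² recovery uses
20 replicate cohorts of 23,049 markers in the test (60 in the acceptance
script, halving the standard error of the reported mean); the density
plateau is assessed on one 23,049-marker cohort with 8 RR-BLUP and 2
fast-profile MCMC subset replicates per density against a repeated-partition
full-panel reference; the relatedness comparison uses 20 cohorts of 2,000
markers with RR-BLUP (the effect is model-agnostic; the three models'
concordance is established separately). MCMC conditional oracles run 40,000
iterations on 50-marker problems.

## Known limitations

- The simulated h² "truth" is defined on the VanRaden-G scale of the
  cohort's own markers; other G scalings would shift the target.
- The BayesA/BL priors pin one published default heuristic; the cited
  reference implementation exposes many more knobs.
- IBS and G rank pairs concordantly (Spearman ~0.8) but not identically:
  IBS is allele-frequency-sensitive where G is centred.
- With fewer than ~2 subpopulations above the 30-animal threshold the DIST
  design set can be small or empty; this mirrors the design's dependence on
  the realized stratification.
- Single cohort, single generation: no selection response or drift.
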