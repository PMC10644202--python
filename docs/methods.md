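# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## The synthetic progeny trial

The generator emulates a single open-pollinated progeny trial of a
long-lived outcrossing tree: `n_mothers` families, each represented by
`progeny_per_family_per_block` trees in every one of `n_blocks` RCBD
blocks. Default dimensions follow the trial the package was designed
around: 94 families × 5 × 8 = 3760 trees on a 6 m × 3 m grid, ~18,000
biallelic SNPs over hundreds of scaffolds, narrow-sense heritabilities near
0.3–0.4, and roughly a quarter of phenotypes missing through thinning and
mortality.

**Founder haplotypes.** Each scaffold is a first-order binary Markov chain
over loci: target allele frequencies are uniform on
[maf_min + 0.05, 1 − maf_min − 0.05] and the transition probabilities are
solved so the adjacent-locus allele correlation equals exp(−d/δ) with δ =
`ld_decay_bp` (clipped where marginals make the pair infeasible). Because
correlations multiply along a Markov chain, pairwise r² ≈ exp(−2d/δ), so
the fitted decay distance (the r² = 0.1 crossing) lands near δ·ln(10)/2 ≈
1.15 δ before attenuation from binarization pulls it back toward δ — the
realized crossing stays within ±30% of δ, which is the property the tests
pin down. Loci whose realized minor-allele frequency falls below the floor
are repaired by flipping random major-allele carriers.

**Mating.** Mothers are distinct founder-haplotype pairs. Every offspring
receives one recombinant maternal gamete and one recombinant gamete from an
unrecorded father drawn uniformly from the founder pool — open pollination
with unknown paternity, which makes families half-sib (expected additive
relationship 1/4, verified against the VanRaden matrix). Recombination is a
Poisson process with one expected crossover per scaffold; the phase of the
two gametes is retained for the phased CNN.

**Traits.** Genetic value = Σ additive effects on the −1/0/1 codes plus Σ
pairwise code products for epistatic pairs; each component is centred and
rescaled so its realized variance fraction equals the configured
`h2_additive` / `h2_epistatic` on a unit total-phenotypic-variance scale.
The bimodal mode re-assigns 80% of the additive budget to one QTL with MAF
in [0.08, 0.2]: the common-homozygote and heterozygote classes then form
two separated phenotype modes (an intermediate-frequency QTL would produce
three blurred classes instead). Visible bimodality therefore requires a
generous additive budget (h² ≳ 0.6), which is how the bimodal demonstration
trait is configured.

**Field.** Blocks are adjacent column strips; families are randomized
within block. The micro-environmental surface is a sum of six random 2-D
cosine components with wavelengths comparable to the field extent, scaled
to `spatial_variance_fraction`; residual noise makes the variance fractions
sum to one. Missingness is uniform Bernoulli — the real process (selective
thinning) is not uniform, so family-size variance after thinning is not
emulated.

**What the generator does not emulate:** genotyping error, allele dropout
and depth-dependent missingness of reduced-representation sequencing;
linkage between scaffolds; selection or non-random mating; spatial
autocorrelation of mortality. Passing tests show the estimators recover the
structure this generator plants, not that they are robust to everything
field data contain.

## Genotype QC

Site filters follow the VCFtools conventions: `--max-missing x` keeps sites
with called proportion ≥ x, MAF and HWE thresholds are lower bounds. The
HWE test is the exact conditional test computed by full enumeration of
heterozygote counts given the minor-allele count (no mid-p correction);
depth-based filters are out of scope because no read-level data exist here.
Imputation is single-site mean (default) or mode — a deliberately naive
stand-in; mean-imputed codes leave the {−1,0,1} grid. PCA is a centred,
unscaled SVD. LD is composite r² (squared genotype correlation), which is
oracle-checkable directly from the coded vectors; the decay curve is a
local quadratic (loess-style, tricube weights) regression of r² on
distance, with the span chosen from {0.1, …, 1.0} by 4-fold CV minimizing
RMSE (points are subsampled to 4000 for the CV step only). The decay
distance is the first downward crossing of r² = 0.1 on a 400-point grid,
linearly interpolated; an absent crossing returns None. Genome size uses 1
pg = 0.978 × 10⁹ bp.

## Spatial adjustment

A penalized tensor-product cubic B-spline surface with (12, 13) knots per
axis and second-order difference penalties on the coefficient grid. The
single smoothing parameter maximizes the restricted likelihood over a
25-point log-spaced grid; the REML score uses the standard partially
improper prior formulation (flat on the 4-dimensional penalty null space).
The exact spline parameterization of dedicated field-trial software is not
reproduced — any smooth low-rank surface estimator with REML-chosen
smoothness serves the purpose, and the knot counts are kept as defaults.
Adjustment subtracts the fitted surface per trait independently; the
Grubbs filter then iterates the two-tailed test at α = 0.05 without
re-adjusting α across iterations, removing the most extreme standardized
deviate (ties → lower index) until no rejection.

## Bayesian alphabet

All five families share single-site Gibbs updates with scaled-inverse-χ²
variance priors; hyperparameter scales are solved from a prior variance
partition R² = 0.5 with df = 5 (the convention of the standard R
implementation these models are usually run in). BayesB/C use exclusion
probability π (default 0.5, configurable); the Bayesian LASSO uses the
exponential-mixture (double-exponential) parameterization with a Gamma
hyperprior on λ², its rate set so E[λ²] matches the usual suggestion
2(1−R²)/R² · Σvar(xⱼ). Chain defaults are 20,000 iterations / 5,000
burn-in / thin 5 and are config-exposed; the benchmark uses shorter chains
(3,000/1,000) because prediction is insensitive to chain length well before
variance components are.

Genomic heritability uses σ²ₐ = σ²_β · Σⱼ var(xⱼ) (the marker-variance sum;
var(Xβ̂) is recorded alongside as an alternative) and σ²ᵧ = σ²ₐ + σ²_ε by
default, with the raw sample variance of y available as an option. "Ten
iterations" is read as ten independently seeded chains, averaged.

A caveat the tests document explicitly: under the R² = 0.5 / df = 5 prior,
a pure-noise trait does **not** estimate h² ≈ 0 — direct 2-D numerical
integration of the posterior (an independent oracle the sampler matches to
<5%) puts the null posterior mean near 0.2 at n = 100–300. The prior
dominates when the data carry no signal; null and planted traits remain
clearly separated, which is what the test asserts.

## Kernel models

VanRaden A = WW′ / 2Σpⱼ(1−pⱼ) with W the column-centred coding
(monomorphic markers excluded from the denominator with a warning). GBLUP
estimates (σ²ᵤ, σ²_ε) by REML through the spectral decomposition of the
training kernel, profiling everything down to the log variance ratio and
optimizing it by bounded scalar search; validation predictions are the
conditional mean μ̂ + K_vt(K_tt + λI)⁻¹(y_t − μ̂), λ = σ²_ε/σ²ᵤ — fully
deterministic, hence the single-replicate rule. With fixed variance
components this reproduces marker ridge regression exactly (Woodbury
identity), which the tests check to 10⁻⁶.

The Gaussian kernel divides squared Euclidean distances by their
off-diagonal mean before applying the bandwidth (h = 1 default): the raw
exp(−d²) form underflows for thousands of markers, and the normalized form
keeps h = 1 meaningful across marker-set sizes; the raw form remains
available. RKHS regression runs a Gibbs sampler in the eigenbasis of the
training kernel (the rotated coefficients have independent scalar
conditionals, so the sweep is vectorized) and predicts by the conditional
mean under posterior-mean variance components. One kernel is used
(L = 1). With the additive kernel and a data-consistent prior partition it
reproduces GBLUP (r > 0.99 in tests); with the Gaussian kernel it picks up
epistatic signal that additive marker models miss — the directional
contrast the benchmark and acceptance suites measure.

## GWAS marker selection

The scan is deliberately a single-locus EMMAX-style approximation rather
than a multi-locus empirical-Bayes pipeline: subset selection only needs a
p-value ranking, and the single-rotation GLS scan is oracle-checkable
(with identity kinship it equals plain linear regression to 10⁻⁶). The
null model y = Wδ + u + ε (W = intercept + 4 genotype PCs, u with
covariance ∝ VanRaden A of the training fold) is fitted once by REML; each
SNP is tested by GLS on the rotated data with Wald p-values on n − q − 1
df. LOD = n·log₁₀(RSS₀/RSS₁)/2, rank-concordant with p by construction;
LOD = 3 is kept as a reporting flag only. FDR adjustment is
Benjamini–Hochberg. Top-k selection takes the k smallest p-values with
ties broken by genome order, and a polymorphism check confirms selected
SNPs segregate within the training fold.

## Benchmark

Validation size is ⌈n/4⌉ (so n = 281 → 71). Splits are independent seeded
partitions, not family-stratified — mirroring the analysed design, whose
mother-sharing between train and validation inflates predictive ability; a
stratified mode exists as an off-by-default flag. Scaling is fitted on the
training fold only: phenotypes and genotypes are standardized for the
Bayesian linear models and the unphased CNN; tree methods are left
unscaled entirely; GBLUP, RKHS and the phased CNN scale the phenotype but
not the genotype input (the kernels and the 0/1 phase layers are used
raw). Degenerate (zero-variance) predictions yield no predictive ability
and are flagged rather than counted in medians. The deviation-from-zero
test is the one-sample Wilcoxon signed-rank (robust, no normality
assumption). The closed-form model count honours the GBLUP
single-replicate rule and the CNN full-set exclusion; at the study design
(12 methods, 10 × 10, subsets {48, 96, 192, all}, 2 traits) it gives 8480.

The CNNs are a compact NumPy implementation (im2col convolutions, ReLU,
max-pooling, a dropout dense head, Adam): genomic marker subsets of ≤ a few
hundred SNPs and a few hundred trees need no framework, and the
implementation keeps initialization, batching and dropout on a single
seeded generator so training is bit-reproducible. The phased variant runs
the same stack on each gamete layer with shared weights and collapses the
phase axis by mean pooling before the dense head; feeding it two identical
layers reproduces the unphased network exactly after an affine first-layer
re-mapping, which is tested. Hyperparameters come from a seeded random
search over declared spaces (8 parameters per gradient-boosting backend,
7 for the CNNs, 5 for the random forest) with 3-fold inner CV maximizing
Pearson r; a constant-response inner fold scores 0 with a warning.

## Problem sizes and determinism

The test and acceptance suites run the full pipeline at desk scale —
hundreds of trees and hundreds of markers rather than thousands — sizes at
which every statistical property checked (oracle equivalences, recovery of
planted heritability, LD decay and spatial variance, null calibration,
directional method contrasts) is already measurable. All randomness flows
from explicit seeds: the simulator spawns named substreams from one master
seed, the numba Gibbs kernel seeds its own generator, and the benchmark
derives per-(split, replicate, method) seeds deterministically, so reruns
are bit-identical.

## Known limitations

- Single-site imputation ignores haplotype information; downstream results
  on data with substantial missingness will differ from haplotype-aware
  imputation.
- The composite-LD r² on unphased codes is not the EM haplotype r²; the
  two differ most at low MAF.
- The spatial model has no block or pedigree random effects and no
  autoregressive residual structure.
- The EMMAX-style single rotation slightly misestimates per-SNP variance
  ratios when a SNP has a large effect; this matters for effect estimates,
  not for the ranking used here.
- The CNN architectures are small reconstructions constrained by the
  phase-pooling rule, not reproductions of any specific published stack.
- Predictive abilities measured on simulated half-sib data inherit the
  mother-sharing optimism of unstratified splits; they are comparable
  across methods, not transferable to other populations.
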