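# Methods

This note documents the statistical model behind `ssimpute`, the choices the
implementation makes where the method leaves room, and what the synthetic
data generator does and does not emulate.

## Model and assumptions

For a standardized continuous phenotype and standardized genotype dosages,
per-SNV association Z-statistics are treated as jointly multivariate normal
with correlation structure equal to the LD (dosage correlation) between
variants. The Z-statistic of an untyped variant u given tag statistics
**z** is imputed by the conditional mean ẑ_u = c'C⁻¹**z**, which assumes:

* effects are small (so z ≈ a√N holds and the covariance of statistics is
  the genotype correlation);
* the target variant is conditionally independent of the trait given its
  tags (imputation under the null of no residual signal — imputed statistics
  of genuinely causal untyped variants are therefore *attenuated*, by
  design, rather than inflated);
* the reference panel and the GWAS cohort share the same LD structure.

Imputed Z-statistics are deliberately **not** divided by the imputation
quality: quality is itself a noisy estimate from a finite panel, and
de-attenuating P-values would risk over-stating associations. The
standardized *effect* is de-attenuated (division by d'D⁻¹d below), because
there the goal is an unbiased point estimate rather than a calibrated test.
An experimental flag exposes Z-rescaling for sensitivity analyses; it is off
by default.

## Shrinkage

Tag–tag correlation matrices routinely have more tags than panel
individuals, so `C` is shrunk: C_λ = (1−λ)C + λI and c_λ = (1−λ)c. λ = 0.1
is the default; λ = 2/√n (capped at 1) and a user value are selectable.
Linear systems are solved by Cholesky factorisation of C_λ (never explicit
inversion); if factorisation fails (λ = 0 with duplicate tags) the solver
falls back to a pseudo-inverse with a logged warning.

## Imputation quality

r²_pred = c_λ'C_λ⁻¹c_λ estimates the squared correlation between the imputed
and the unobserved direct statistic. Raw values can exceed 1 through
sampling noise near λ = 0 and are clamped to [0, 1] (the raw value is kept in
debug logs). The adjusted version corrects for the panel-size/parameter
ratio using the effective number of tags q_eff, computed as the number of
leading eigenvalues of the tag correlation matrix needed to reach 99.5% of
its trace (threshold configurable). The adjustment is clamped at 0 from
below and returns 0 with a warning when n ≤ q_eff + 1. Downstream scans gate
on r²_pred,adj ≥ 0.3 by default; all results are written regardless, with a
pass/fail flag.

## Variable sample size and missingness

With per-tag sample sizes N_k (all subsets of a complete sample of N_max
individuals), the correlation between observed statistics is attenuated by
δ_kl = N_{k∩l}/√(N_k N_l). The overlap N_{k∩l} is rarely published, so two
bracketing assumptions are provided: maximal overlap
(δ = min(√(N_k/N_l), √(N_l/N_k)), mode `dependent`) and random overlap
(δ = √(N_k N_l)/N_max, mode `independent`); an exact overlap matrix can be
supplied (mode `known`). `dependent` is the default: real meta-analyses
show missingness correlations near the maximum (a SNV is typically missing
from a whole cohort, not from random individuals), and it is the
conservative choice since it minimises the imputed statistic.

Construction order: shrink first, then attenuate (D = C_λ ∘ δ with the
diagonal reset to 1; d built from c_λ). This keeps mode `none` *exactly*
(bitwise) equal to the base method, which the tests assert.

The standardized effect is â_u = ẑ_u/(√N_max · d'D⁻¹d). Because
E[ẑ_u] = quality · α√N_max, the division by the quality de-attenuates the
effect estimate; below a quality floor of 10⁻⁴ the effect is reported as
NaN (the Z-statistic is still reported) since dividing by a noise-level
quality produces arbitrarily large effects. When directly observed
statistics on N_u < N_max individuals are compared against imputed ones,
they are rescaled by √(N_max/N_u).

## Windowing

Imputation proceeds per chromosome in core windows of 1 Mb with 250 kb
flanks: all harmonized tags in core+flank form one shrunk LD system, reused
for every target inside the core. The window grid starts at the smallest
tag position rounded down to a multiple of the core size — deterministic and
data-independent. Targets are panel variants with MAF ≥ 0.1% (configurable;
an explicit target list bypasses the MAF filter) that do not share a
position with a tag. Leave-one-out evaluation (`mask_and_impute`) instead
takes all tags within ±750 kb of the focal variant. Windows with zero tags
report quality 0 and no Z.

## Harmonisation

Records are matched to the panel on (chromosome, position); the effect
allele is aligned to the panel's alt allele, flipping the sign of z when the
coding is reversed. Palindromic variants (A/T, C/G) are excluded by default
— strand cannot be resolved from alleles alone and is never guessed.
Mismatching allele pairs are excluded; duplicates keep the first occurrence.
Every input record ends up either aligned or in the exclusion log with a
reason, and harmonisation is idempotent. Missing panel genotypes are
mean-imputed per variant before any correlation estimate, keeping C a valid
correlation matrix without dropping individuals. Positions are 1-based;
window arithmetic uses half-open intervals.

## Conditional analysis and the locus scan

The conditional statistic is the standardized residual
z_cond = (z_u − c'C⁻¹z_S)/√(1 − c'C⁻¹c) with shrunk panel LD — equivalent
to the summary-based approximate conditional regression under the
standardized-trait assumptions the pipeline already makes. When the
residual variance falls below 10⁻³ (near-perfect LD with the conditioning
set) the result is flagged non-estimable rather than inflated. The scan
screens imputed variants with r²_pred,adj ≥ 0.3 and P ≤ 10⁻⁸, conditions
each on all reported variants within 1 Mb of the significant span, and
declares a candidate locus when any conditional P stays below threshold;
the top variant is the smallest conditional P (ties: position, then id).
Adjacent-window loci are merged when the weaker top variant is explained by
the stronger one. No per-variant sample-size adjustment is applied at the
conditional stage beyond what imputation already did.

## Synthetic data

The generator emulates the statistical structure of the validation
experiments, not human genome sequence:

* **Genotypes**: equicorrelated LD blocks; each variant is the sum of two
  latent-Gaussian haplotypes thresholded at the MAF quantile. Thresholding
  attenuates correlation, so the latent correlation is calibrated via the
  bivariate-normal orthant probability so that the realised dosage
  correlation matches the requested r. MAF is constant within a block
  (making any target r attainable); blocks and regions are mutually
  independent. Defaults: 80 variants per region in blocks of 4–8,
  within-block r ~ U(0.6, 0.95), MAF ~ U(0.1, 0.5), 80% of variants typed
  ("tags", emulating dense HapMap-style tagging of a well-covered region)
  and one untyped causal variant per region in a block with at least two
  tags.
* **Phenotype**: y = Σ√h2_i g̃_i + e with Var(e) = 1 − Σh2; default
  h2 = 0.02 for a single causal variant (0.0001 in the power experiment,
  typical of a weak GWAS effect).
* **Sample sizes**: drawn from a very heterogeneous ("wide",
  log-uniform over [13, 110219]) or homogeneous ("narrow", uniform over
  [50000, 187167]) distribution, rescaled so the distribution maximum maps
  to the simulated GWAS size, and clipped to ≥ 1.
* **Missingness**: each variant's observed set has exactly N_k individuals;
  an individual's inclusion score interpolates between a shared random
  ordering (θ_miss = 1: fully nested sets, maximal overlap) and an
  independent uniform draw (θ_miss = 0: hypergeometric overlap N_kN_l/n).
  The interpolation is monotone in θ_miss and exact at both endpoints.
* **GWAS**: per-variant standardized regression on that variant's observed
  subset (a = g̃'ỹ/N_k, z = a√N_k), matching the model the imputation
  assumes.

What this does **not** capture: realistic recombination maps and
allele-frequency spectra, polygenic architectures (single causal variant
only), cross-ancestry panel mismatch, rare variants (MAF range bounded away
from 0 for numerical stability of block calibration), and non-linear
(haplotype) tagging. Passing tests therefore demonstrate the estimators'
statistical behaviour under the assumed model, not performance on real
cohort data.

All randomness flows from one integer seed through spawned substreams, so
each stage is independently reproducible and identical seeds give
byte-identical outputs.

## Problem sizes of the shipped experiments

The validation experiments run at desk scale: 10 regions of 80 variants,
25000-individual cohorts split half/half into LD panel and GWAS for the
missingness study in its full configuration, reduced to 5000 individuals
(2500 GWAS) with 150 replicates per cell in the automated checks; 12500
GWAS individuals with a 2500-individual LD panel for the power comparison
(150 replicates per LD level) and the locus scan (100 replicates); 10⁵
variant pairs for the LD-noise simulation. Medians across regions are used
for MSE comparisons, matching how the estimators' behaviour is summarised.

## Known limitations

* The quality metric inherits the panel's LD estimation error and is
  conservative for small panels; an out-of-sample ridge-regression quality
  estimator is a documented extension point, not implemented.
* λ is global per run; locally adaptive shrinkage (recombination-aware
  banding, thresholding of small correlations) is out of scope.
* Chromosome X, genome-build liftover, multi-allelic sites (split/skip
  only) and phased-haplotype handling are not supported.
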