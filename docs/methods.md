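# Methods

## Synthetic study generator

The generator emulates an exon-sequencing association study of unrelated
individuals drawn from several differentiated populations.

**Population structure.** Allele frequencies follow the Balding–Nichols
model: for ancestral minor-allele frequency *p* and drift *F* ∈ [0, 1), each
population's frequency is Beta(*p*(1−*F*)/*F*, (1−*p*)(1−*F*)/*F*), with
mean *p* and variance *F p*(1−*p*). The default is 7 populations of sizes
(100, …, 97) totalling 697 individuals with *F* = 0.1, a plausible
magnitude for continental human differentiation. With *F* = 0 every
population uses the ancestral frequency exactly.

**Genotypes.** Each individual receives two allele draws per SNP
(Hardy–Weinberg), so marginals are Binomial(2, population frequency).
Within a gene, two mechanisms create linkage-disequilibrium-like
correlation while preserving those marginals:

- a Gaussian copula on allele draws: within one allele draw, the latent
  normals of a gene's SNPs share a factor with loading √`ld_rho`;
- comonotone drift: when a gene has `ld_rho > 0`, its SNPs' population
  frequencies are generated from a *shared* beta quantile per population,
  i.e. linked SNPs differentiate together, as drift acting on a common
  haplotype background would cause. (With `ld_rho = 0` the per-SNP draws
  are independent.)

Defaults give within-gene genotype correlations around 0.35–0.55 for common
SNP pairs, which puts construct reliability (Cronbach's α) near 0.5 — the
range in which one-factor gene constructs are informative but not trivial.
Private variants are realised as a single heterozygous carrier.

**Trait and replicates.** Q1 = Σ βⱼ·gⱼ + 0.03·Age + 0.60·Sex + 0.65·Smoke
+ N(0, 1), with Age ~ U(20, 70) and Sex, Smoke ~ Bernoulli(0.5) fixed
across replicates. The default study has 9 causal genes carrying 39 causal
SNPs (base per-allele effects 0.18–0.40 trait units on common SNPs, 2–2.5×
larger on rare SNPs) plus 12 non-causal decoy genes; total 93 SNPs, far
below a real exome panel but sufficient to exercise every stage at desk
scale. Only the noise term is redrawn between replicates, so genotypes,
covariates and the genetic signal are bit-identical across replicates.

The per-gene effect sizes and covariate coefficients are the generator's
own design choices (no published values exist for them): they are set so
every structural path has standardized magnitude ≈ 0.15–0.4 — stably
estimable at n = 697 — except the weakest gene (HIF1A, β_std ≈ 0.1), kept
near the noise floor deliberately so the replicate evaluation reproduces
the characteristic instability of weak path coefficients.

**What the generator does not model:** sequencing error, missingness,
family structure, haplotype-phase LD decay with distance, and selection.
Passing tests therefore certify the statistical machinery under a clean,
correctly specified architecture, not performance on real exome data.

## Stage 1 screen

Each tested column is regressed on the trait with OLS
(trait ~ intercept + column + covariates); p-values are two-sided from the
t distribution with n − k degrees of freedom. Collapsing replaces each
gene's rare SNPs (MAF < 0.05 by default) with a carrier indicator (1 if the
individual carries ≥ 1 rare minor allele in the gene — "indicator coding"
with equal weights); a rare-allele-count coding is available behind
`collapse_coding="count"`. The Bonferroni threshold is α divided by the
number of columns actually tested in the given configuration, so it changes
when collapsing changes the test count. Genes with at least one column at
p ≤ threshold are the PIGs; TP/FP/FN counts per replicate compare PIGs to
the generator's causal list.

Stratification adjustment uses principal components of the column-centered
(not variance-scaled) additive genotype matrix, computed by SVD; score
columns are sign-fixed (largest-magnitude entry positive) and ordered by
decreasing eigenvalue. One caveat at desk scale: with only ~100 SNPs, top
PCs partially align with the strongest causal loci and absorb their signal,
so the pipeline default adjusts for 2 PCs; on a realistically large panel
the conventional 8–12 PCs (all configurable) behave as expected. Note also
that an ancestral MAF near 0.05 can realise on either side of the
rare/common boundary in a finite sample; classification always uses the
realised MAF and the stated threshold.

## SEM engine

**Model form.** All-y LISREL-style: observed indicators y load on latents
(y = Λη + ε), latents regress on each other and on exogenous observed
covariates (η = Βη + Γx + ζ). An observed variable that receives a path
(the trait) is promoted to a phantom latent with unit loading and zero
measurement residual, so its disturbance is the regression residual. The
implied covariance over (y, x) is

Σ_yy = Λ(I−Β)⁻¹(ΓΦΓᵀ+Ψ)(I−Β)⁻ᵀΛᵀ + Θ, Σ_yx = Λ(I−Β)⁻¹ΓΦ, Σ_xx = Φ,

with Φ saturated and free. Mean structure is not modeled (the fit
statistics used are covariance-based); missing rows are dropped listwise
(the intended inputs are complete).

**Identification.** Default: the first listed indicator of each latent is
the marker (loading fixed to 1); a `std` statement fixes the latent
variance to 1 instead. Exogenous latents covary freely by default
(saturated block); other covariances are declared with `covary`.

**Estimation.** The normal-theory discrepancy
F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p* is minimized by Fisher scoring
(expected-information Newton steps with Armijo halving) with an L-BFGS
fallback, starting from marker-scaled moment estimates. Free variances are
optimized as log-variances, which keeps them positive; a variance driven to
the boundary (Heywood case) leaves the fit flagged inadmissible.
Convergence requires max|gradient| < 1e-6 (500 iterations cap);
non-convergence is returned as a flagged fit with diagnostics, never
silently. T = (n−1)·F_ML at the optimum (the n convention is switchable);
df = p*(p*+1)/2 − free parameters.

**Standard errors.** Naive SEs from the inverse expected information
divided by (n−1). Robust SEs are the sandwich
(ΔᵀWΔ)⁻¹ΔᵀWΓ̂WΔ(ΔᵀWΔ)⁻¹/(n−1), where Δ = ∂vech Σ/∂θ, W is the
normal-theory weight ½Dᵀ(Σ̂⁻¹⊗Σ̂⁻¹)D, and Γ̂ is the empirical covariance of
vech[(z−z̄)(z−z̄)ᵀ] (fourth moments). The mean-scaled statistic divides T
by c = tr(UΓ̂)/df with U = W − WΔ(ΔᵀWΔ)⁻¹ΔᵀW; under multivariate normality
c ≈ 1. A rank-deficient fourth-moment matrix triggers a warning and a
fallback to naive SEs. Genotype indicators (0/1/2, including near-constant
rare variants) are treated as continuous — precisely the situation the
robust corrections are for; ordinal-indicator estimation is out of scope.

**Fit indices.** With baseline = independence model (closed form:
F_b = Σ ln s_ii − ln|S|): CFI = 1 − max(T−df,0)/max(T_b−df_b, T−df, 0);
RMSEA = √(max(T−df,0)/(df(n−1))), undefined (NaN) at df = 0;
SRMR = root mean square of (s_ij−σ̂_ij)/√(s_ii s_jj) over unique pairs
including diagonals. Both the unscaled and mean-scaled variants of
CFI/RMSEA are reported and labeled, since either χ² convention is seen in
practice. Cutoffs: CFI ≥ 0.95 good / ≥ 0.90 acceptable; RMSEA ≤ 0.06 good /
≤ 0.10 acceptable; SRMR ≤ 0.08 good / < 0.10 acceptable.

**Standardization.** Every estimate is rescaled by the implied standard
deviations of its connected variables; standardized SEs follow by the delta
method (numerical Jacobian of the standardization map against the
estimate covariance). R² of an endogenous variable is 1 − its standardized
disturbance (or residual) variance. The standardized value of a marker
loading is an estimated quantity even though its raw value is fixed.

## Construct building

Stage-1 p-values rank a gene's SNPs; a greedy pass keeps a SNP only if its
LD r² (squared Pearson correlation of additive codes) with every kept SNP
is ≤ 0.8, stopping at `max_indicators` (default 6; the pipeline default
uses 3). Ties break by SNP id, making selection deterministic and
permutation-invariant. Eigenvalue profiles of the SNP correlation matrix
and Cronbach's α report how factorable each construct is. The assembled
model text (one latent per gene, optional PopStr latent, gene→trait and
covariate→trait paths) always parses and is identified by construction.

## Replicate evaluation

The reference replicate's standardized estimates and SEs serve as
population values; the same model is refit on every other replicate and
relative bias 100·|est − pop|/|pop| (plus its signed variant) is averaged
per parameter, per class and overall. Absolute bias is used for the
headline number so "≤ 5%" is a one-sided, testable bound; signed means are
emitted alongside. Comparisons are on the standardized solution, which
makes the report scale-invariant; parameters whose population value is
(structurally or numerically) zero — e.g. exogenous latent variances that
standardize to exactly 1 with zero SE — are excluded and listed. The
overall MRB averages the four substantive classes (loadings Λ, indicator
residuals ε, disturbances ζ, paths Β/Γ); the saturated latent-covariance
and covariate-covariance blocks, whose population values are near zero by
construction, are reported per class but not folded into the headline
number. Non-converged replicates are dropped with a warning; more than 20%
of them is a hard error. Either naive or robust SEs can be the compared
quantity (`se_kind`).

Because genotypes are fixed across replicates, measurement-side parameters
are nearly replicate-invariant (MRB well under 2%), while path coefficients
— the only parameters that depend on the redrawn trait — carry most of the
bias (≈ 15–25%), and the weakest path is the worst. The overall MRB of the
default study lands between 3% and 5% across seeds, driven by the
class composition above.

## Numerical and scale choices

Problem sizes throughout (93 SNPs, 27-indicator acceptance model, 100
replicates, 200-fit recovery studies) are chosen so the full suite runs on
one CPU in a few minutes while keeping every Monte-Carlo check at ≥ 3
standard errors of resolution. The sample covariance uses ddof = 1; a
non-positive-definite input raises unless an explicit ridge is requested.
The reference SEM cross-check in the test suite is an independent
minimal implementation (explicit pattern matrices, derivative-free
optimization) written solely as an oracle; it shares no code with the
engine.
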