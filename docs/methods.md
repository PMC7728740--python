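# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `gwpred`, and what the synthetic-data experiments do and do not show.

## Data model

Genotypes are biallelic SNP dosages *x ∈ {0, 1, 2}* (count of the tracked
allele; ALT for VCF input), with missing calls allowed until QC. Marker QC
removes markers with MAF < `maf_min` (MAF = min(p, 1−p) over non-missing
samples) or missing fraction > `missing_max`, optionally retains a seeded
random subset, and imputes remaining missing dosages to the column mean, so
every downstream model sees a complete (possibly fractional) matrix. Mean
imputation is the conventional default for genomic-prediction matrices; no
LD-aware imputation is attempted. Phenotypes are assumed pre-corrected for
design effects (blocks, environments); the package fits no fixed effects
beyond an intercept.

## Relationship matrices and kernels

- Additive (VanRaden): *A = WW′ / 2Σpᵢqᵢ* with *W = X − 2pᵢ*. Monomorphic
  markers contribute zero; an all-monomorphic panel is an error.
- Dominance (heterozygosity-deviation / Su-style): column *i* of *W_d* is
  1{x=1} − 2pᵢqᵢ and *D = W_dW_d′ / Σ2pᵢqᵢ(1−2pᵢqᵢ)*. The heterozygosity
  indicator is exact equality with 1, so fractional imputed dosages
  contribute 0 to the dominance design — a documented approximation.
- Gaussian kernel: pairwise squared Euclidean distances between dosage rows
  are divided by their maximum (normalized range [0, 1]) and
  *K = exp(−h·d²)*. The division by the maximum realizes the stated [0, 1]
  normalization exactly; the bandwidth default is h = 0.5 and is not tuned.
  Cross-kernel blocks for held-out samples reuse the *training* maximum.
- PSD repair: solvers add 1e−8 to kernel diagonals before factorization.

## REML variance components

`fit_reml` maximizes the restricted likelihood of y = 1μ + Σₖ gₖ + ε,
gₖ ~ N(0, Kₖσₖ²), over one or two genetic kernels plus a residual. The
update scheme is EM warm-up (5 iterations; monotone and boundary-safe)
followed by average-information Newton steps with three safeguards: (i) a
component driven below the boundary 1e−6·var(y) is clamped there and the AI
step is re-solved in the free coordinates; (ii) a step that decreases the
restricted likelihood falls back to EM; (iii) convergence is declared on
either likelihood change < `tol` or parameter change < 1e−8·var(y) — the
latter matters at the zero boundary where the likelihood flattens long
before EM steps become small. Standard errors are the square roots of the
inverse AI matrix diagonal; ratio standard errors (h², H², h²ₐ, h²_d) use
the delta method. A kernel set that aliases the residual (e.g. K = I) makes
the AI matrix singular and is rejected up front. Identification of σ²ₐ under
a null trait depends on the eigen-spread of A: panels with n > p or family
structure identify the boundary sharply, while p ≫ n panels leave σ̂²ₐ
noticeably noisy — the tests use n > p for null-boundary checks for this
reason.

## Bayesian alphabet samplers

All five models share the centered additive design (W = X − 2pᵢ; the
intercept absorbs the mean, predictions are invariant) and single-site Gibbs
updates with conjugate full conditionals: Normal for μ and each effect,
scaled-inverse-χ² for variances, inverse-Gaussian mixing for the LASSO's
τⱼ², Bernoulli for inclusion indicators, Beta for π (Cπ). Spike-and-slab
updates integrate the effect out of the inclusion odds. The dominance term,
when enabled, uses a BRR-style common-variance Normal prior on the centered
{0,1,0} design for every model family — the source models specify priors for
additive effects only, and ridge shrinkage is the neutral choice.

Hyperparameter defaults: df_a = df_e = 5; S_a set so the prior mode of the
marker variance equals 0.5·var(y)/Σ2pᵢqᵢ, S_e so the prior mode of the
residual variance is 0.5·var(y); Bayes B has fixed π = 0.95 (proportion of
null markers), Bayes Cπ samples π under a uniform Beta prior; the BL
regularization λ² gets a Gamma(1.1, 0.1) prior. The desk-scale default chain
is 30 000 iterations / 5 000 burn-in / thin 10; the study-scale preset
(10⁶ / 10⁵ / 50) is available as `GibbsConfig.study_scale()` but is not the
test default. Chains are seeded and bitwise reproducible. For validation the
marker and residual variances can be frozen (`fix_marker_var`,
`fix_resid_var`), which turns BRR into an exactly conjugate model with a
closed-form posterior to test against.

## Kernel BLUP

`fit_kernel_blup` solves Henderson's equations at plugged-in variance ratios
(REML-estimated if not supplied): ĝₖ = σₖ²KₖV⁻¹(y − 1μ̂), μ̂ the GLS
intercept. With the VanRaden A this is identical to marker ridge regression
with penalty λ = 2Σpᵢqᵢ·σₑ²/σₐ² (the RR-BLUP/GBLUP equivalence, used as an
oracle in the tests). Held-out samples are predicted by kernel interpolation
ĝ_new = K_cross K_train⁻¹ ĝ_train, the standard GBLUP extension when new
individuals are genotyped with the same markers. RKHS fits use the same REML
machinery on the Gaussian kernel — a plug-in equivalent of the fully
Bayesian kernel regressions used elsewhere; both return kernel BLUPs at
estimated variance ratios.

## Bayesian-regularized networks

The BRNN objective is F(w) = β·E_D + 2α·E_W with E_D = Σr² and E_W = ½Σw²,
minimized by Levenberg–Marquardt on the Gauss–Newton approximation
H = 2βJ′J + 2αI. After accepted steps the evidence framework re-estimates
the hyperparameters: γ_eff = k − 2α·tr(H⁻¹) ∈ [0, k] (effective number of
parameters), α ← γ_eff/2E_W, β ← (n − γ_eff)/2E_D. Defaults: α = 0.01,
β = 1, up to 1000 epochs, inputs and targets standardized internally.

Two numerical points: (i) LM acceptance uses the trust-region quality ratio
(actual/predicted reduction ≥ 0.25) rather than a bare decrease test —
for purelin architectures the Gauss–Newton model is exact along the
weight-rescaling manifold (w₁w₂ constant) but blind to its bilinear
curvature, and a bare decrease test accepts long near-flat steps that stall
convergence; (ii) up to five accepted LM steps run between evidence updates,
which keeps the (α, β) fixed point from dragging the weight optimization.
Exact LM is quadratic in the weight count and is capped at 20 000 weights;
larger inputs should use marker subsets. The ten presets brnn1–brnn10
follow the published 1–3-layer grid with a final linear output unit.

## LSTM regression

Each individual's marker vector is chunked in genome order into
⌈p/chunk_size⌉ steps of `chunk_size` features (default 100, zero-padded
last chunk); the final hidden state feeds a scalar linear head. The cell is
the standard gate parameterization with W/R/b concatenated over (i, f, g, o);
the state activation (tanh default, ReLU variant) applies to both the cell
candidate g and the output transform h = o·act(C), matching the cited
ReLU-LSTM strategy, whose identity initialization is applied to the
cell-candidate recurrent block (other gates Glorot; tanh networks get the
standard forget-bias 1). Training is mini-batch Adam (lr 0.005, gradient
norm clip 1.0, 100 epochs default) on hand-derived BPTT gradients that are
checked against central finite differences (with a 1e−8 absolute floor for
entries where finite differences are roundoff-dominated). Mini-batches of
size ⌈fraction·n⌉ partition a fresh shuffle each epoch, so a 100% fraction
performs one update per epoch — the update-step count, not wall-clock, is
what the timing property asserts. Presets lstm1–lstm6 span
{ReLU, Tanh} × {10%, 50%, 100%}. Hidden size defaults to 32 (not stated in
the source grid).

## SNP-effect back-solving

Given centered genetic values â and the centered design Z, the scan iterates
û_t = D_tZ′(ZD_tZ′)⁻¹â from D₀ = I, re-weights D*ₜ₊₁ = diag(ûᵢ²·2pᵢqᵢ) and
renormalizes tr(D) = p, for three iterations. Column centering puts the ones
vector in the null space of ZDZ′, so the zero-jitter path uses a
minimum-norm (lstsq) solve — which also realizes the exact interpolation
identity Zû = â and the pseudoinverse oracle; the default jitter is
1e−8·mean(diag(ZDZ′)). An uncentered mode is provided. QTL calling is a
plain threshold on |û| at a chosen iteration; thresholds are trait-specific
and deliberately a required user input.

## Cross-validation and model comparison

`run_cv` draws one seeded split per cycle — round(0.9·n) training samples,
reproducing 290/32 and 581/65 at n = 322 and 646 — shared by all models
(paired design; sharper contrasts, documented choice). Every model trains
strictly on the training split: allele frequencies, scaling constants and
variance components are all re-estimated per cycle. Constant validation
predictions yield a missing PA with a warning rather than NaN propagation.
Desk-scale defaults are 10 cycles with reduced chains/epochs; the 50-cycle
protocol is a parameter, not a different code path. Tukey–Kramer comparisons
compute studentized-range statistics with the unequal-n correction against
`scipy.stats.studentized_range` quantiles; compact letters come from maximal
cliques of the non-significance graph, so models share a letter iff they are
mutually non-different. PA values are compared untransformed (no Fisher z),
matching standard reporting; a z-transform can be applied by the caller.

## Synthetic data: what it emulates, and what it does not

`simulate_genotypes` draws marker frequencies uniformly on a MAF range
(default 0.05–0.5) across 10 chromosomes; `ld_rho` induces AR(1) latent-
haplotype correlation along chromosomes; family mode draws two parents per
full-sib family and transmits one parental allele per locus (unlinked
transmission — family LD beyond allele sharing is not modeled).
`simulate_trait` places `n_qtl` large-effect QTL carrying `qtl_share`
(default 0.9) of the additive variance, specified by variance explained
(effects ∝ 1/√2pq with ±20% jitter and random sign) so that no nominal QTL
is a near-null signal, a Normal polygenic background on the remaining
markers, optional dominance effects on the QTL, and rescales every component
to its *realized* target variance (total phenotypic variance 1), giving
exact desk-scale recovery targets such as var(BV) = h²ₐ and
corr(y, BV) = h·(1 + O(n⁻½)).

Two synthetic study populations are used in the end-to-end checks, both
500 × 2000 with 10 QTL and h²ₐ = 0.5:

- an **unstructured diversity panel** (no LD, no families) for variance
  components and SNP-effect recovery — effects are exactly localizable
  because markers are independent;
- a **family-structured panel** (50 full-sib families × 10 offspring,
  ld_rho = 0.6) for cross-validation model comparison — validation
  individuals have relatives in training, which is the regime in which
  breeding-program prediction (and in particular the high-capacity LSTM)
  operates; on panels of unrelated individuals the LSTM memorizes training
  data and transfers nothing, and linear methods are bounded by
  n/(n + effective marker count).

Passing tests on these panels therefore demonstrates correctness of the
algorithms and qualitative behavior (signal vs null discrimination, QTL
recovery, effect sharpening), not predictive performance on any real
population: real panels have LD decay, allele-frequency spectra, genotyping
error and G×E structure the generator does not model.

## Problem sizes and runtime

The test and reproduction runs use n = 500, p = 2000, 10 CV cycles,
3000-iteration Gibbs chains and 30-epoch LSTM training as the package's
desk-scale defaults; study-scale settings (50 cycles, 10⁶-iteration chains)
are configuration presets. All computations are single-threaded CPU.

## Known limitations

- Dominance designs ignore fractional imputed dosages (exact-heterozygote
  indicator).
- BRNN training is exact LM — quadratic memory in weight count; no
  stochastic variant is provided.
- The Gibbs samplers report posterior means only; no convergence
  diagnostics beyond optional effect-sample storage.
- `predict_blup` interpolates within the training kernel's column space;
  individuals genetically outside it shrink to the mean.
- Multi-allelic sites, G×E interaction, epistasis and spatial/block effects
  are out of scope.
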