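# Methods

## Data model

A cohort is a pedigree (`animal,sire,dam` CSV; `0`/empty = unknown
parent) plus a phenotype table (`animal,pond,<traits>`; empty cell =
missing). Ten traits are handled: two subjective colour scores
(uncooked on 1–4, cooked on 1–3), six colorimetric traits (L\*, a\*, b\*
for uncooked and cooked shrimp) and two growth traits (body weight,
body length). Input order of pedigree records is never trusted; a
topological sort runs on every load, unknown parents become unrelated,
non-inbred phantom founders, and no genetic-group effects are fitted
(the source population is treated as a single population).

## Relationship matrices

`a_matrix` builds **A** by the tabular method
(A_ii = 1 + ½A_sd, A_ij = ½(A_js + A_jd)); `inbreeding_coefficients`
implements the Meuwissen–Luo ancestor-accumulation algorithm, and
`a_inverse` assembles the sparse A⁻¹ directly from Henderson's rules
with the Mendelian-sampling variances d_i = ½ − ¼(F_s + F_d) (¾ − ¼F
with one known parent, 1 with none). Tests verify A against a
gene-dropping Monte-Carlo oracle and A⁻¹ against dense inversion.

## Linear animal model (continuous traits)

The model is y_ij = µ + Pond_j + a_i + ε_ij with pond fixed (intercept
plus full-rank dummies, first pond as reference; records with missing
pond are rejected), a ~ N(0, σ²ᴬA) and ε ~ N(0, σ²ₑI). Records missing
the trait are dropped; animals without records still receive EBVs
through the pedigree.

**Estimation.** With M = ZAZ′ the covariance among records is
V = σ²ᴬM + σ²ₑI. One eigendecomposition M = UDU′ rotates the data so V
is diagonal, making every restricted-likelihood, score and
average-information evaluation O(np²). The fit itself is
average-information REML on the log-variance scale with step-halving, a
trust region of 4 log-units, a multiplicative EM-like fallback when the
AI step fails, and KKT handling of the zero boundary (a component
pinned at the variance floor, 10⁻¹⁰ of the phenotypic variance, with a
negative score is treated as converged). Convergence requires
|Δlogℓ| < 10⁻⁸ and relative parameter change < 10⁻⁶ (max 100
iterations); non-convergence is flagged on the result, never raised.
Standard errors come from the inverse AI matrix, se(h²) by the delta
method. Tests confirm the optimum coincides (to ~10⁻⁸) with a
derivative-free maximisation of the explicit dense-V restricted
likelihood, including at the σ²ᴬ = 0 boundary.

**EBVs.** BLUPs solve the mixed-model equations at the REML estimates
using the sparse pedigree A⁻¹; optional reliabilities are
1 − PEV_i/((1+F_i)σ²ᴬ) from the inverse coefficient matrix. Equality
with dense GLS/BLUP algebra is tested to 10⁻⁸.

**Bivariate model.** Complete-case records (both traits present) share
the same rotation, so the restricted likelihood factorises into n 2×2
blocks Σ_i = d_iG + E. G and E are optimised through their Cholesky
factors (PSD by construction) with L-BFGS-B; r_g = covᴬ/√(σ²ᴬ₁σ²ᴬ₂) is
clamped to [−1, 1] with a boundary flag, r_p uses the summed
covariances, and se(r_g) comes from the numerical observed information
in covariance coordinates via the delta method. The univariate fit uses
the literal AI-REML update; for the bivariate fit a quasi-Newton search
on the Cholesky scale was chosen instead because it is simpler to keep
PSD and equally accurate at these problem sizes.

## Threshold model (ordinal scores)

Scores arise from a latent liability crossing ordered thresholds:
P(Y_ij ≤ k) = logistic(θ_k − (Pond_j + a_i)), the proportional-odds
model with a pedigree-structured random effect and the residual fixed
at the standard-logistic variance π²/3 (forced by the liability-h²
definition h² = σ²ᴬ/(σ²ᴬ + π²/3)). There is no separate intercept —
the c−1 free thresholds absorb location, ponds are reference-coded.
The latent-liability sign convention is used (larger a ⇒ higher/darker
category); the equivalent form θ_k + Pond + a differs only by negating
the effects, and this choice keeps liability EBVs on the same sign as
continuous-trait EBVs.

**Estimation** is nested Laplace: for trial σ²ᴬ, Newton iterations with
the analytic gradient and Hessian (verified against numerical
differentiation) maximise the joint penalised log-likelihood over
(θ, β, a); the approximate marginal likelihood
ℓ_pen − (q/2)·log σ²ᴬ − ½·log|−H| is then maximised over log σ²ᴬ by
bounded 1-D search with warm-started inner solves. H is the full joint
Hessian — integrating the fixed effects as well as the breeding values,
the REML analogue — which measurably reduces the downward bias of the
plain random-effects Laplace on these data. se(σ²ᴬ) and a 95% interval
come from the curvature of the marginal likelihood in log σ²ᴬ.

**Known bias.** With a single ordinal record per animal, Laplace-type
estimators are biased downward: in the recovery tests (50 study-size
replicates, generating σ²ᴬ = 0.46, liability h² = 0.123) the mean
estimated liability h² is ≈ 0.09–0.10. The tests assert recovery within
0.05 on the h² scale and ≥80% coverage of the (wide) 95% intervals;
users comparing against MCMC or PQL-based mixed-model packages should
expect method-dependent σ²ᴬ for ordinal traits.

**Ordinal trait pairs.** No bivariate ordinal REML is provided
(mirroring the software limitation the original analysis worked
around); any pair involving an ordinal trait uses the Pearson
correlation of EBVs. These are attenuated toward zero at low EBV
reliability — with h² ≈ 0.12 and this family structure the attenuation
is substantial (observed ≈0.3–0.45 for a generating r_g of 0.77) — so
they are labelled `ebv_pearson` in all outputs and should be read as
sign/ranking evidence, not unbiased estimates.

## Selection response

CR_y = r_g·h_x·h_y·SD_y and %IS = 100·r_g·h_x/h_y. SD_y defaults to 1
(responses in genetic-SD units): the published response table
reproduces at 2 dp from its printed h² and r_g columns only under
SD_y = 1, even for traits whose phenotypic SD differs from 1, so that
convention is the default and a per-trait SD can be passed for
unit-scaled responses. When reproducing the published table the rounded
printed inputs are used (matching evident practice); full-precision
estimates are used otherwise, with rounding applied only at
presentation. `verify_response_by_simulation` checks the closed form by
truncation-selecting both parental sexes on the x phenotype, mating at
random, and measuring offspring mean breeding value in y per unit
realized selection intensity.

## Colorimetry

sRGB → linear RGB (IEC 61966-2-1 gamma) → XYZ (D65, 2° observer) → CIE
L\*a\*b\* (1976). The conversion matrix rows sum to the white point only
to ~10⁻⁷, so L\* is clamped to [0, 100]. Per-animal colour is the
arithmetic mean of per-pixel Lab values (averaging in the perceptual
space, not mean-RGB-then-convert; the two differ and the choice is
tested). Scoring repeatability is the Pearson correlation of paired
category codes treated as numeric, reconstructed from confusion-matrix
counts — this reproduces the published study-chart values 0.81 and 0.92
exactly. Two published cells do not reproduce from their printed
counts: the third study-chart pair computes 0.81 vs printed 0.80, and
the commercial-chart counts give ≈0.72/0.64/0.62 vs printed
0.78/0.71/0.68 (the commercial table tabulates only categories 9–11, so
off-range scores appear to be omitted); only the two exactly
reproducible cells are asserted.

## Synthetic cohorts

The generator reproduces the study conditions: 55 sires × 52 dams, 67
families (every sire and dam used at least once, the remainder drawn at
random — producing half-sib structure), 838 progeny allocated evenly,
7 ponds assigned uniformly. Breeding values follow the
Mendelian-sampling recursion a_i = ½(a_s + a_d) + m_i with
m_i ~ N(0, ½(1 − (F_s+F_d)/2)G) and founders ~ N(0, G). G is assembled
from the published additive variances and genetic correlations (the
published correlation matrix is PSD as printed; a nearest-PSD
projection is applied defensively), E from the residual variances and
the residual covariances implied by the phenotypic correlations, with
ordinal liability residuals independent logistic (variance π²/3).
Ordinal thresholds are solved by Gauss–Hermite quadrature + root
finding so the marginal score frequencies match the published
distribution. Pond-effect magnitudes are not published; the default —
an invented value — is 0.3 phenotypic SD per trait, drawn N(0, sd²) but
fitted as fixed effects. Identical seeds give bit-identical datasets.

What the generator does **not** emulate: growth over the 124–143-day
grow-out, pond water quality, maternal/common-environment effects
beyond pond, genotype-by-environment interaction, measurement error in
the colorimetric pipeline, and pixel-level images. Passing recovery
tests therefore demonstrate correctness of the estimation machinery
under the stated model, not robustness to the real data's departures
from it.

## Problem sizes and numerical choices

Recovery experiments use 50 seeded replicates at the study size (945
animals) for the linear, bivariate and ordinal models and 20 replicates
of 10⁴ parents for the truncation-selection check; oracle comparisons
use pedigrees of ≤ 200 animals where dense algebra is exact and cheap.
The variance floor (10⁻¹⁰ of phenotypic variance) keeps the genetic
side of the mixed-model equations solvable at the boundary; σ²ᴬ for the
ordinal model is searched in [10⁻⁴, 30] on the log scale. Presentation
rounding (2 dp for h², correlations, CR, %IS; 1 dp for CV%) is applied
only when writing tables, never fed back into computation.
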