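# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data generator and the standing Monte-Carlo experiments that
validate the package, including what those experiments do and do not
demonstrate about real data.

## Setting and assumptions

The package implements two-sample summary-data Mendelian randomization:
instrument–exposure effects (b_X, se_X) and instrument–outcome effects
(b_Y, se_Y) come from non-overlapping GWAS cohorts and are combined per
SNP. Validity rests on the three instrumental-variable assumptions —
relevance, independence from confounders, and exclusion (no pathway to
the outcome except through the exposure). The estimators differ in how
much exclusion failure (horizontal pleiotropy) they tolerate. Betas for
binary outcomes are treated as log-odds throughout, so exp(beta) is an
odds ratio; no attempt is made to convert between scales.

Mediation follows the two-step product-of-coefficients design: the
candidate chain X → M → Y requires (1) a causal X→M effect, (2) a causal
M→Y effect, and (3) a causal X→Y effect with no evidence of reverse
causality. All three conditions are recorded per candidate.

## Instrument selection

- Association threshold p < 1e-5 (the "suggestive" threshold customary
  for microbiome and immune-trait GWAS, whose top signals rarely reach
  5e-8).
- Greedy LD clumping at r² < 0.001 within 10,000 kb. SNPs are visited
  in ascending (p, rsID) order — the rsID tie-break makes the pass
  deterministic and input-order invariant. An LD pair absent from the
  table is treated as r² = 0, matching the sparsity convention of
  pairwise LD exports. The reference panel is an input, never bundled.
- Per-SNP variance explained R² = 2·MAF·(1−MAF)·β² (standardized-trait
  form). An alternative reading that divides by se² circulates in
  applied reports; it is exposed as `snp_r2(..., formula="beta_over_se")`
  so the choice is explicit, but the standard form is the default.
- Trait-level strength F = ((N−k−1)/k)·(R²_total/(1−R²_total)) with
  R²_total the sum of per-SNP R². The weak-instrument rule excludes the
  whole trait when F < 10; F exactly 10 is retained (the exclusion rule
  is strict). SNPs with missing EAF contribute 0 to R²_total.

## Harmonization

Records are matched by rsID (both supported data sources carry rsIDs;
positions are not used as a key). Outcome alleles that are the exact
swap of the exposure's flip the outcome beta and complement the EAF;
strand-complement matches are resolved likewise but only for single-base
alleles — complementing a multi-base allele is ill-defined, so indels
match only exactly or as an exact swap. Palindromic SNPs (A/T, C/G) are
kept only when both allele frequencies lie outside [0.42, 0.58]
(window 0.08) and orientation is then inferred from minor-allele
concordance; otherwise they are dropped as ambiguous. Every drop is
counted by reason and surfaced in errors. These rules follow common
two-sample MR practice and are package assumptions, not data-derived.

## Estimators

**IVW.** Closed form beta = Σ b_X b_Y/se_Y² / Σ b_X²/se_Y², identical to
the zero-intercept WLS slope. Default standard error is multiplicative
random effects: the fixed SE times max(1, sqrt(Q/(k−1))), so observed
heterogeneity widens but never narrows intervals. k = 1 delegates to the
Wald ratio (beta = b_Y/b_X, se = |se_Y/b_X|, first-order delta method).

**MR-Egger.** 1/se_Y²-weighted regression with intercept, after jointly
flipping (b_X, b_Y) signs so all b_X ≥ 0. The fit itself is delegated to
statsmodels WLS; the residual scale is bounded below by 1 before
computing standard errors (same under-dispersion rule as IVW). The
intercept, its SE and two-sided normal p constitute the directional-
pleiotropy test; the slope is consistent for θ under InSIDE
(pleiotropy independent of instrument strength).

**Weighted median.** Per-SNP ratios β_j = b_Yj/b_Xj with weights
w_j = (b_Xj/se_Yj)². The estimate interpolates the centered cumulative
weights s_j = (cum_j − w_j/2)/Σw at probability 0.5 — the fixed,
documented percentile rule against which the test-suite oracle (a
plain-loop transcription) checks. SE by seeded parametric bootstrap
(resampling b_X and b_Y from their sampling distributions).

**Weighted mode.** Gaussian-kernel weighted density over the ratios,
bandwidth = factor × 0.9·min(sd, 1.4826·MAD)·k^(−1/5) (modified
Silverman, MAD-based, with a tiny floor for degenerate spreads). The
argmax is located on a 512-point grid and refined by two 4-step zooms so
grid resolution never limits the estimate on wide ratio ranges. SE by
the same bootstrap.

**Bayesian weighted MR.** Generative model b_Xj ~ N(γ_j, se_Xj²),
b_Yj ~ N(θγ_j, se_Yj² + τ²), θ ~ N(0, 10²). An EM-style iteration
alternates (i) the Gaussian posterior of each γ_j, (ii) the posterior
mean/variance of θ, (iii) inlier responsibilities w_j from a
two-component model of standardized residuals (N(0,1) inlier vs
N(0, 5²) heavy tail, prior outlier mass 0.05), and (iv) a moment update
of τ². The working precision weight is u_j = w_j + (1−w_j)/25 — the
exact EM weight for a Gaussian scale mixture — so outliers keep 1/25 of
their precision instead of being zeroed; plain responsibility weighting
can otherwise starve the iteration on strongly heterogeneous inputs
(every point flagged an outlier, τ² collapsing). Convergence is |Δθ| <
1e-8 within 500 iterations; non-convergence raises an error carrying
the last iterate. Because the prior has a fixed scale, this estimator is
only approximately equivariant to rescaling of the outcome (exact for
the four frequentist estimators) and modeling the exposure-side
measurement error makes it the one estimator here that is not diluted
by weak instruments.

p-values are two-sided normal on beta/se for every method (bootstrap SEs
included), floored at 1e-300; the 95% CI multiplier is fixed at
1.959963985 for bit-stable outputs.

## Diagnostics

Cochran's Q at the fixed-effect IVW beta with first-order weights
(b_X/se_Y)², df = k−1; the Egger residual Q with df = k−2 (never larger
than the IVW Q — adding a free intercept cannot increase the weighted
residual sum); the Egger intercept test; leave-one-out IVW with an
influence flag when omitting a SNP flips the pooled sign or moves it by
more than one SE *of the refit* (the refit's own SE is the yardstick: a
gross outlier inflates the full-set random-effects SE and would
otherwise mask itself); and per-SNP Wald ratios. Heterogeneity and
pleiotropy clearance (p > 0.05) are recorded as booleans and never
silently filter results. Note the first-order Q weights ignore se_X, so
with a modest exposure GWAS and a nonzero causal effect Q picks up
genuine extra ratio variance; this is expected behavior, not a defect.

## Screening and mediation pipeline

Forward screen: each exposure is instrumented, harmonized and fitted;
tiers come from the primary (IVW) p-value — significant < 0.01,
suggestive < 0.05, both strict. Per-exposure failures (no instruments,
weak F, empty harmonization) are recorded with reasons; a batch never
aborts. No multiplicity correction is applied, matching the screening
convention this reproduces; a Benjamini–Hochberg q-value column is
emitted for information only. Reverse screen: the outcome trait is
instrumented under the same rules and tested against each tiered
exposure; clearance requires reverse IVW p > 0.05, and an untestable
reverse leg (no instruments) is conservatively marked not clear.
Bayesian gate: significant traits need bwmr p < 0.05; a boundary p
exactly at the threshold demotes (strict rule), as does a missing or
non-convergent fit. Mediator search applies the same machinery to both
legs (exposure instruments for X→M, the mediator's own instruments for
M→Y, Bayes gate on the M→Y leg) and decomposes against the exposure's
total effect.

Mediation arithmetic: mediated = β₁·β₂ exactly; direct is *stored* as
total − mediated, so the identity direct + mediated = total holds at the
bit level as computed (re-adding the floats can round by an ulp for
pathological magnitudes). The proportion 100·β₁β₂/β_total is reported
only for sign-consistent decompositions — a sign-discordant mediated
path is printed "/" with the note "opposite to the overall trend" — and
flagged ">100%" when the mediated effect exceeds the total. Dividing
printed, rounded betas (−0.016 by −0.216) gives 7.41%; a report quoting
7.26% for the same pair must have divided unrounded values, so printed
tables alone cannot reproduce such figures exactly. The delta-method SE
sqrt(β₂²se₁² + β₁²se₂²) is an extension beyond the basic decomposition
and is labelled as such. Univariable MR estimates β₂; multivariable
direct-effect estimation is out of scope.

## Synthetic data generator

Per SNP: maf ~ U(maf_range); γ ~ N(0, gamma_sd²) (optionally folded
positive for designs that need stable allele orientation);
se_X = 1/sqrt(2·maf·(1−maf)·N_exposure); b_X = γ + noise; pleiotropy
α = 0, N(0, sd²) (balanced) or N(mean, sd²) (directional) on a
configurable invalid fraction, independent of γ unless the
InSIDE-violation knob is set; b_Y = θγ + α + noise with the analogous
se_Y. p-values are two-sided normal. LD blocks replicate a lead SNP's γ
across members 10 kb apart with configured pairwise r², giving clumping
something real to remove. Mediation triples add mediator-specific
instruments δ ~ N(0, delta_sd²): the mediator sees β₁γ and δ, the
outcome sees (direct + β₁β₂)γ and β₂δ. Everything is byte-reproducible
from (config, seed).

Defaults emulate the scale of a published microbiome → biobank screen:
N_exposure = 7,738, N_outcome = 412,181, mediator GWAS N = 3,757,
100 SNPs, gamma_sd = 0.15, maf in (0.05, 0.5).

What the generator does **not** emulate: case–control imbalance of a
binary outcome (the SE model is the standardized-trait approximation
1/sqrt(2·maf(1−maf)N)), linkage beyond block-constant r², sample overlap
between cohorts, population stratification, and winner's-curse-inducing
discovery/replication structure. Passing tests therefore demonstrate
estimator and pipeline correctness under the stated model, not immunity
to those real-data pathologies.

## Experiment designs and their rationale

The standing experiments (`mrmediate.experiments`) fix their own
simulation designs:

| experiment | design | why |
|---|---|---|
| type-I calibration | defaults, θ=0, 100 SNPs, 500 reps | under θ=0 the first-order weights are exact, so IVW/Egger/Q should reject at ~5% |
| clean recovery | γ_sd=0.2, N_exp=500k, N_out=412k, 200 reps | strong instruments make weak-instrument attenuation (≈ θ·se_X²/γ_sd²) negligible against the Monte-Carlo SE, isolating estimator consistency |
| contaminated recovery | 30 SNPs, 40% invalid, directional α mean 0.1, γ folded positive | per-SNP pleiotropy 2.5× the causal path θ·γ_sd; positive orientation makes the pleiotropy bias IVW upward |
| Egger directional | α ~ N(0.05, 0.02²), θ=0, instruments pre-selected at p<1e-5 | selection removes near-null instruments whose orientation sign-flips would attenuate the intercept |
| balanced pleiotropy | α ~ N(0, 0.02²), θ=0.1, strong design, 500 reps | InSIDE holds: slope recovers θ, intercept test stays at its nominal level |
| mediation recovery | β₁=0.1, β₂=0.25, direct=0.1 (proportion 20%), mediator N=20k, δ_sd=0.3 | keeps exposure-SNP leakage into the mediator's instrument set (and its winner's curse) negligible, so the two-step proportion is recovered cleanly |

On the contaminated arm the weighted median is *not* unbiased: with a
40% invalid count the random instrument weights cross the 50% breakdown
point in a material fraction of replicates, and even below breakdown the
weighted 0.5-quantile of a one-sidedly contaminated sample sits at the
~0.83 quantile of the valid ratios, a bias that scales with the ratio
spread exactly as the estimator's sampling SD does. The robustness
claim validated is therefore: weighted-median error ≤ 0.05 (25% of θ)
while IVW's error exceeds both that tolerance and three times the
median's error. Replicate studies consume point estimates only, so
bootstrap SEs are skipped there; the full estimators (with bootstrap)
run in the pipeline tests.

## Known limitations

- No proxy-SNP lookup for instruments missing in the outcome, no
  Steiger directionality filtering, no MR-PRESSO, no multivariable MR.
- The Bayesian estimator is this package's own EM formulation of the
  weighted-outlier model, validated against its contract (fixed-IVW
  equivalence on clean data, outlier robustness) rather than against any
  external implementation; exact replication of other software's
  Bayesian p-values is not promised.
- The reverse-causality check is only as good as the outcome trait's own
  instruments; when the outcome's associated variants are the exposure's
  instruments (as in a minimal simulation), the reverse leg inherits the
  forward signal.
- F-statistics require per-SNP sample sizes; without an N column the
  weak-instrument filter is skipped with F recorded as NaN.
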