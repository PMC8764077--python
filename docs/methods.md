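# Methods

This note documents the statistical procedures the package implements, the
defaults and tolerances it uses, and the design choices made where the
procedure admitted more than one reasonable construction.

## Data model and validation

The unit of analysis is one survey respondent with two 0–100 intention
scores (COVID-19 vaccine, contact-tracing app), four ordinal motivation
items collected on 0–4, three 0–100 risk-perception items, three 0–100
trust items, and demographic/attitude covariates.  Validation is strictly
complete-case: rows missing any modelled field are dropped and counted,
never imputed, mirroring the exclusion of incomplete questionnaires at the
collection stage.  Bounded fields are range-checked; validation is
idempotent.

Motivation items are collected on 0–4 but modelled on 1–4.  The package
recodes by collapsing the bottom two raw levels (0 and 1) into modelling
level 1.  This is a documented assumption — the two numbering schemes have
no published bridge — and the mapping is overridable
(`dataset.DEFAULT_MOTIVATION_RECODE`).  The long-format table carries both
the recoded and the raw response so the reshape is lossless.

## Bivariate Gaussian distributional regression

The pair (Y1, Y2) is bivariate normal with observation-specific mean,
scales, and correlation; Sigma = D Omega D with D = diag(sigma1, sigma2).
Links: identity for the means, log for the scales, and rhogit(rho) =
rho / sqrt(1 − rho²) for the correlation.  The rhogit inverse eta /
sqrt(1 + eta²) keeps every observation's Sigma positive definite for any
finite coefficients (checked by Cholesky in tests).  The bounded 0–100
outcomes are deliberately modelled as unbounded Gaussians — no censoring
correction — so fitted coefficients read directly as intention points; the
residual Q–Q table is the tool for judging how much the boundary clamping
distorts the fit.

**Estimation.**  All five coefficient blocks are maximised jointly by
L-BFGS (analytic gradient; BFGS polish if the projected-gradient norm
exceeds 1e−6 relative), with a rank check per design block that names
collinear columns.  Asymptotic covariance comes from a central-difference
Hessian of the analytic gradient.  A likelihood identity — the bivariate
log-density equals the marginal-times-conditional decomposition — is
enforced to 1e−10 in tests, and freezing the correlation block at zero
reproduces two independent OLS fits exactly.

**Sampling.**  Blockwise Gaussian random-walk Metropolis, one block per
distribution parameter, proposal covariance equal to the block's ML
covariance times an adapted scalar (target acceptance 0.234, adaptation
every 50 iterations during burn-in only, so the retained chain is a valid
Markov chain).  Priors on regression coefficients are flat; the spline
penalty acts as the only Gaussian prior.  Defaults are 10,000 iterations
with 1,000 burn-in; summaries are posterior means with 2.5–97.5% percentile
credible intervals, and an interval excluding zero is flagged (the tables'
bold convention).  An acceptance rate below 1% in any block raises a
sampler error rather than returning a silently broken chain.

**Age smooth.**  One-dimensional thin-plate regression spline, built by the
standard low-rank eigen-construction: radial basis r³/12 over the (thinned,
at most 100) unique covariate values, the 5 leading-magnitude eigenvectors
retained, the polynomial null-space constraint absorbed by an SVD
reparameterisation, columns rescaled to unit standard deviation (the
penalty transformed accordingly) and centred so the smooth is orthogonal to
the intercept.  Five bases therefore yield 4 design columns: 3 penalized
wiggly directions plus the unpenalized linear term.  A single smoothing
parameter shared by all blocks carrying the smooth is chosen on a
log-spaced grid (1e−4 … 1e6) by a Laplace approximation to the marginal
likelihood at the ML stage and held fixed during MCMC; with only three
penalized directions the fit is insensitive to this choice well beyond an
order of magnitude.

**Model comparison.**  DIC = D̄ + p_D with D(θ) = −2 log L(θ) (unpenalized
likelihood), D̄ the posterior-mean deviance over the (evenly thinned, at
most 4,000) retained draws, and p_D = D̄ − D at the posterior-mean
parameters.  Forward selection greedily adds the candidate covariate that
most reduces DIC, entering it into all five blocks simultaneously — the
"same covariates for every parameter" convention — and stops when no
candidate improves; ties within 0.01 go to the earlier-listed candidate.

## Factor scores and categorical codings

Each 3-item block gets a one-factor maximum-likelihood solution on the
empirical variance–covariance matrix (correlation-based fitting is
available as an option): the ML discrepancy log|Σ| + tr(SΣ⁻¹) − log|S| − p
is minimised directly over loadings and log-uniquenesses (Nelder–Mead from
a principal-axis start, two polish passes), the loading sign fixed so the
loading sum is positive.  Explained variance is Σλ²/trace(S).  Uniquenesses
are floored at 1e−3 times the item variance with a Heywood warning.  Scores
are regression (Thomson) scores, Σ̂⁻¹λ applied to centred items, which have
mean zero over the fitting sample by construction.  The scikit-learn EM
factor analyser serves as an independent cross-check in tests, not as the
implementation.

Terciles use the inverse-ECDF (type-1) quantile at 1/3 and 2/3, giving
integer bounds on integer data; intervals are lower-open/upper-closed with
the first interval closed on the left, so boundary values fall into the
lower-indexed category and every value maps to exactly one class.  The
doubts coder assigns exact zeros to "No doubts" and terciles the strictly
positive remainder.  More than n/3 ties at a boundary, or an empty zero
class, warn rather than fail.

## Mixed cumulative logistic model

Proportional odds with the printed sign convention logit P(Y ≤ k) = θ_k −
(x'β + γ): a positive β means higher categories are more likely, so
exp(β) is the odds ratio of a *higher* motivation score.  The published
fixed-effects equation also carries a Gaussian residual ε inside the logit;
this is treated as notational — the logistic latent error of the standard
proportional-odds model plays that role — matching the model family of the
software the original analysis used.

The subject random intercept is integrated out by adaptive Gauss–Hermite
quadrature (15 nodes by default): a vectorised Newton search finds each
subject's posterior mode of the integrand, the local curvature sets the
node scaling, and the log-likelihood is assembled by log-sum-exp.  At
σ_γ = 0 the code takes the exact fixed-effects path, so the reduction is an
identity, not a limit; doubling the node count moves a toy log-likelihood
by less than 1e−8.  Optimisation is over (θ₁, log-threshold-gaps, β,
log σ_γ), guaranteeing ordered thresholds; Wald covariance is a numerical
Hessian in the natural (θ, β) parameterisation at the optimum.  AIC counts
thresholds, fixed effects, and the variance component; a greedy AIC forward
search mirrors the DIC search.  The conspiracy model is the same likelihood
without the random intercept, on respondent-level rows with 7 outcome
levels.  A crude separation screen warns when a binary covariate perfectly
predicts an extreme category.

## Descriptive layer

Continuous strata comparisons use Wilcoxon rank-sum (2 strata) or
Kruskal–Wallis (>2); categorical tables use Pearson's chi-squared without
continuity correction, switching to Fisher's exact test whenever any
expected cell count is below 10 — the switch is a pure function of the
expected-count table.  For tables larger than 2×2, where no exact Fisher
implementation is available in the Python stack, the Fisher branch uses a
seeded Monte-Carlo permutation of the table conditional on its margins,
ordered by conditional table probability (20,000 draws).  The
vaccine-versus-CTA comparison is implemented as the *paired* signed-rank
test, since the same respondents answered both questions; an unpaired
variant is provided.  Spearman correlations use midranks.

## Synthetic data: what it does and does not emulate

The generator reproduces the structures the models assume, with defaults
fixed at the study conditions: n = 448, 70.8% female, age 33.8 ± 13.9
(truncated to 18–90 and rounded), a 0.219 exact-zero share for the doubts
score (the "no doubts" fraction) with a scaled Beta(1.2, 2.2) remainder on
(0, 100], risk and trust item blocks driven by one latent standard-normal
factor each (item = loading × factor + unique noise, rescaled to the 0–100
range; risk loads weakest on perceived likelihood, strongest on scare),
intentions drawn from the bivariate distributional law given each
respondent's doubts, risk, trust, and flu-vaccination status and then
clamped to [0, 100] — which produces the boundary spikes real intention
data show — and motivation items drawn from the mixed ordinal law with a
positive risk effect and σ_γ = 1.2.  The true coefficient defaults are
fixed so the generated medians, correlation, and effect directions match
the observed survey's shape (vaccine intentions higher and more
doubts-sensitive than CTA intentions).

Not emulated: the empirical joint distribution of the real survey beyond
these structures — item-level response styles, the exact age–class mix,
cluster effects of snowball recruitment.  Passing tests therefore
demonstrate that the estimators recover the laws they assume and that the
pipeline's mechanics are correct, not that the real data satisfy those
laws; the clamping of intentions is in fact a deliberate, known violation
whose footprint the Q–Q diagnostics display.  One global seed drives
independent substreams per stage, so any stage can be regenerated in
isolation and a fixed seed fixes every generated byte.

## Numerical choices and degenerate inputs

Log-scale linear predictors are clipped at ±40 inside the likelihood to
keep the optimiser's surface finite; ML convergence demands a relative
gradient norm below 1e−6 (hard failure at 1e−3); quantile intervals require
at least 100 retained draws; cell probabilities in the ordinal likelihood
are floored at 1e−300 before logging.  Degenerate inputs fail loudly and
specifically: missing columns and unseen factor levels name the offender,
out-of-range values name the row, constant outcomes and singular
covariances raise estimation errors, all-tied score vectors produce a
single-category coding with a warning.  The rank check rejects duplicated
design columns at fit time; the invariance of the likelihood itself to an
appended zero column (with zero coefficient) is asserted at the evaluator
level in tests.

## Problem sizes used by the test suite

Statistical assertions run at sizes chosen to make Monte-Carlo bounds
sharp but cheap: likelihood identities on 100 randomized instances;
ML recovery at n = 5,000 (3 asymptotic SEs); credible-interval calibration
over 100 replicates at n = 300 with 1,500-iteration chains; DIC selection
over 100 replicates with 1,000-iteration chains; ordinal recovery at 500
subjects × 4 responses; descriptive null calibration over 1,000 permuted
replicates.  The full published-scale MCMC (10,000 iterations at n = 448)
runs in `scripts/acceptance.py`.

## Known limitations

- No censoring correction for the 0–100 boundaries; coefficients are
  attenuated in proportion to the clamped mass, as the diagnostics show.
- DIC and AIC are the only comparison criteria; no cross-validation.
- Smoothing parameters are fixed at their ML-stage values during MCMC, so
  posterior bands for the smooth do not propagate smoothing uncertainty.
- The Monte-Carlo Fisher p-value for r×c tables carries simulation noise
  of order 1/√20,000 and is seeded for reproducibility.
- One factor per item block, no rotations or multi-factor solutions; the
  proportional-odds model has no partial-odds or random-slope variants.
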