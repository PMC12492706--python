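# Methods

## Model

A bulk measurement of feature *j* in sample *i* is modeled as a
proportion-weighted combination of latent per-sample cell-type levels plus
i.i.d. measurement noise:

    X_ij = w_i' Z_ij + e_ij,        E[e_ij] = 0,  Var[e_ij] = tau_j^2
    Z_ij = mu_j + eps_ij,           E[eps_ij] = 0,  Var[eps_ij] = Sigma_j

with `w_i` a known k-simplex vector of cell-type proportions (estimated
upstream by a reference-based method), `mu_j >= 0` the mean cell-type levels
of the feature, `Sigma_j` a symmetric PSD k x k cell-type covariance, and
`tau_j^2 >= 0` the technical-noise variance. No distributional assumption is
made for estimation; the tensor estimator additionally assumes approximate
normality of the bulk levels. Inputs must be on a linear scale (CPM-like
expression or methylation beta values): a log transform breaks the linear
mixing structure, so the package warns when expression-like input looks
log-scaled but never transforms it.

## Tensor estimator

Given fitted parameters, the cell-type-level estimate is the conditional
expectation of `Z_ij` given the observed bulk value:

    zhat_ij = E[Z|theta] + Sigma_j w_i (x_ij - E[X_ij]) / (w_i' Sigma_j w_i + tau_j^2)

The residual between observed and expected bulk is distributed back to cell
types along `Sigma_j w_i`, so the covariance structure — not only
abundance — decides which cell types absorb the signal. The conditional
covariance `Sigma - (Sigma w)(Sigma w)'/(w'Sigma w + tau^2)` quantifies the
remaining uncertainty. When `w'Sigma w + tau^2 <= 1e-12` the feature carries
no deconvolvable signal and the estimator returns the prior mean with a
logged warning. `estimator_covariance` gives the model-implied across-sample
covariance of the estimates, `mean_i Sigma w_i w_i' Sigma / (w_i'Sigma w_i +
tau^2)` — the large-sample covariance the estimated tensor exhibits. Under a
`Sigma = I, tau^2 = 0` ablation this quantity is the same for every feature,
which is why a covariance-blind estimator cannot recover feature-specific
covariance structure; the full model's version tracks `Sigma_j`.

Covariates enter per the package's convention: cell-level covariates shift
each cell type's mean inside the mixture (`mu_jh + c1_i' gamma_jh`), and
tissue-level covariates add to the bulk expectation (`c2_i' beta_j`). With
zero covariates everything reduces to the core model. The conditional mean
`E[Z|theta]` includes the cell-level covariate offsets.

## Estimation

Parameters are fitted per feature by iteratively re-weighted moment
matching. Two sample-specific moment conditions, `E[X_ij] - x_ij` and
`Var[X_ij] - (x_ij - E[X_ij])^2`, both have expectation zero at the truth;
with a diagonal weight matrix the quadratic-form objective reduces to
weighted least squares.

* **Outlier mask.** Samples more than `outlier_sd` (default 2) standard
  deviations from the per-feature mean are excluded once, up front, from
  the raw values. A zero-variance feature keeps all samples.
* **Means.** `x` is regressed on the design `[W | W*c1 | C2]` by weighted
  least squares with `mu >= 0` (active-set NNLS / bounded least squares);
  covariate effects are unconstrained. Rank-deficient designs get a small
  ridge with a logged warning.
* **Variances.** The penalized objective
  `sum_i u_i [(w_i'Sigma w_i + tau^2) - r_i^2]^2 + lambda(||Sigma||_F^2 + tau^4)`
  is exactly quadratic in the free entries of `(Sigma, tau^2)`, so it is
  solved in closed form (ridge-regularized weighted normal equations). Only
  when that solution violates the PSD cone or `tau^2 >= 0` does a smooth
  refinement run, parameterizing `Sigma = LL'`, `tau^2 = t^2` (feasible by
  construction) and minimizing with L-BFGS-B and analytic gradients from the
  eigenvalue-clipped projection. `lambda` defaults to `1e-4 x (feature
  variance)^2` so it scales with data units.
* **Weights.** After each iteration, `u_i = clip(1 / max(vhat_i, eps),
  floor, cap)` normalized to mean 1, where `vhat_i` is the model-predicted
  bulk variance — samples whose variance the current parameters predict
  poorly are down-weighted. Defaults: floor `1e-4`, cap `1e4`.
* **Schedule.** Two mean iterations and three variance iterations
  (`{fit_means; fit_variances; update_weights}` twice, then
  `{fit_variances; update_weights}` three times). Each mean iteration
  refreshes the variance estimate so the weight update reflects the current
  parameters.
* **Determinism.** Fitting processes samples in a canonical internal order
  (sorted by sample ID), making results exactly invariant to the order in
  which samples arrive, and is bit-reproducible for fixed inputs.

### Identifiability of (Sigma, tau^2)

Because proportion rows sum to 1, `(1'w)^2 = 1` for every sample, so the
model-implied variance is invariant under

    Sigma -> Sigma + c 11',   tau^2 -> tau^2 - c.

The data cannot choose `c`; the L2 penalty does. After any constrained
refinement the package re-selects, in closed form, the feasible `c`
minimizing `||Sigma + c 11'||_F^2 + (tau^2 - c)^2` (`_gauge_fix`), so the
reported parameters are the unique minimum-penalty representative of the
equivalence class, independent of optimizer path. Two consequences worth
knowing: (i) only gauge-invariant combinations (e.g., `sigma^2 + tau^2` at
k = 1, or `w'Sigma w + tau^2` generally) are estimated without systematic
offset; (ii) recovery benchmarks compare fitted parameters against the
gauge-fixed representative of the generating truth, since the raw generating
`(Sigma, tau^2)` is not an identified target. The same non-identifiability
applies to any method fitting this variance model on simplex proportions.

At the study sizes used here (n = 500, concentrated Dirichlet proportions),
the information in the second-moment conditions is modest: the optimal-GLS
standard error of individual covariance entries is comparable to the entries
themselves, so per-feature covariance estimates are noisy by necessity, and
across-feature correlations of covariance entries plateau around 0.6-0.7.
Means are far better determined (correlations with truth >= 0.99 per cell
type). Larger cohorts or more dispersed proportions tighten the covariance
estimates roughly as 1/sqrt(n).

## Association testing

The phenotype enters the bulk-level model directly ("one-step"; no tensor
point estimates are formed):

    X_ij = sum_h w_ih (mu_jh + delta_jh y_i + c1_i' gamma_jh) + c2_i' beta_j + noise

with per-sample noise variance `w_i'Sigma_j w_i + tau_j^2` taken from the
prior fit. `delta_jh` is estimated by weighted least squares with inverse
model-implied variances, so high-uncertainty samples are down-weighted.
The parametric mode reports normal-theory t p-values; the asymptotic
(distribution-free) mode keeps the identical point estimates and swaps in an
HC3 sandwich covariance (t reference). The joint tissue-level test is an
F/Wald test of all k phenotype coefficients and reduces exactly to the
marginal t-test at k = 1. Samples masked as outliers during fitting are
excluded from testing; a cell type whose fitted level variance is zero is
assigned p = 1; collinear phenotype terms are flagged and assigned p = 1.

Note that reusing the 2-SD outlier masks slightly attenuates effect
estimates (the mask preferentially removes samples whose phenotype pushed
the bulk into the tails) — about 10-15% at the simulated conditions used in
the tests. This is the cost of the robustness the masking buys.

### Replication framework

For a discovery/validation pair (shared features; intersected otherwise):
discovery hits pass Bonferroni over all tested features (alpha = 0.05);
hits replicating in validation under Bonferroni over the number of hits,
with a consistent effect sign, are true positives, the rest false negatives.
Features with discovery p > 0.95 are negative controls; those significant in
validation under Bonferroni over the number of controls are false positives,
the rest true negatives. Consistency is summarized by MCC (0 when any
marginal sum is zero, flagged when there are no hits) and F1. Direction
consistency applies only to marginal results — the joint test has no single
sign.

## Evaluation statistics

* **Robust correlation** — Pearson correlation implied by a
  minimum-covariance-determinant fit on the best 95% of points (trim
  fraction 0.05); if either vector has zero IQR the correlation is defined
  as 0. Used for all benchmark correlations; a fixed random state makes it
  deterministic.
* **Normalized von Neumann entropy** — entropy of the correlation-matrix
  eigenvalues divided by k, scaled by log k into [0, 1]. Identity
  correlation gives 1 (no covariance structure to exploit), rank-1 gives 0.
  Natural logs internally; the normalization makes the base irrelevant.
  Correlation (not covariance) eigenvalues are used: that is the only
  reading under which these endpoints hold.
* **Root-median-square error** — `sqrt(median((truth - estimate)^2))`;
  robust to a minority of arbitrarily bad entries.
* **delta-log10(p)** — regress the true cell-type level on {bulk, all
  proportion columns, estimate} after log1p scaling and 2-SD trimming;
  report `log10 p(bulk) - log10 p(estimate)` (two-sided t-tests). Positive
  values mean the estimate explains truth beyond what bulk already does. A
  constant estimate gets p = 1; an estimate collinear with bulk takes a
  flagged, regularized path.
* **Moment recovery** — per-feature trimmed (2-SD) empirical moments of the
  true tensor are the gold standard; fitted parameters are correlated with
  them across features (robust correlation), per cell type for means and
  variances and pooled over pairs for covariances.
* **Effect beyond composition** — shift estimates to nonnegative, log1p,
  standardize, then regress on {composition, status}; the status coefficient
  isolates phenotype effects on cell-type levels from composition artifacts
  (a naive bulk-times-proportion estimate shows ~no effect here). Constant
  estimates score 0.

## Synthetic data

The parametric generator draws, per feature, `mu ~ U(0, 10)` per cell type,
a correlation matrix with normalized entropy uniform on [0.2, 0.95]
(convex combination of a random rank-1 sign pattern and the identity,
bisected to the target), per-cell-type standard deviations `cv x (mu + 0.5)`
with a per-feature biological CV uniform on [0.1, 0.3] — emulating the
mean-variance coupling of expression data — and `tau^2 ~ U(0.01, 0.1)`.
Proportions are Dirichlet with decreasing concentration (10, 5, 3, 2, 1,
then halving), mimicking the abundance skew and dispersion of real tissue
composition estimates. Cell-type levels are multivariate normal by default
(making the Gaussian conditioning oracle exact); a moment-matched log-normal
option probes robustness to skew (its correlation matching is approximate
for correlations below about -0.58, where the log-normal construction
saturates). Negative levels are kept (the model is unconstrained);
truncation at zero is opt-in and flagged because it biases the recorded
moments. A phenotype effect adds `delta x y` to targeted cell types, with
`y` standard normal or Bernoulli(1/2).

The resampling generator pairs the complete cell-type profile of one
randomly drawn pool sample with the proportions of another and forms the
exact weighted combination — no added noise, truth tensor recorded;
per-feature parameters are the empirical pool moments. Proportion noise is
logistic-normal: Gaussian noise of the requested SD on log proportions,
renormalized to the simplex.

What these generators do not emulate: count-level sampling noise (UMI
sampling, dropout), compositional zeros, batch structure, or dependence
between features. Passing tests therefore demonstrate correctness of the
machinery and the claimed statistical properties under the model, not
performance on any real cohort.

## Problem sizes and numerical choices

Tests and the acceptance script use n = 400-500 samples, m = 60-2000
features and k = 3-5 cell types; the consistency check averages 20 seeds at
n in {100, 250, 500, 1000} with m = 60. Tolerances: symmetry 1e-10, PSD
-1e-8, degenerate denominators 1e-12, optimizer ftol 1e-15 / gtol 1e-12 on
the rare refinement path. Proportions deviating from the simplex by more
than 1e-2 are rejected; smaller deviations are renormalized with a warning.

## Known limitations

* Covariance estimates are noisy at typical cohort sizes (see the
  identifiability section); treat per-feature `Sigma_j` as shrinkage
  targets, not precise estimates.
* The tensor estimator can produce extreme values (including negative
  levels) for outlying bulk values; nonnegativity of the fitted means does
  not imply nonnegativity of the deconvolved levels.
* The covariate convention (cell-level effects inside the mixture,
  tissue-level additive) is one natural choice; other parameterizations
  exist and are not implemented.
* Cell-type proportions are taken as known; uncertainty in upstream
  composition estimates is not propagated.
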