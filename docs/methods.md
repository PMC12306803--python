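# Methods

## Model

`fgee` fits the marginal function-on-scalar regression

    g( E[ Y_ij(s) | X_ij ] ) = beta_0(s) + sum_r X_ij,r beta_r(s),

where clusters i = 1..N are the independent sampling units (e.g. neurons),
j = 1..n_i indexes longitudinal observations within a cluster (e.g. trials),
and s is a point on a regular, evenly spaced functional domain of length L
(e.g. within-trial time, rescaled internally to [0, 1]). Outcomes may be
continuous (identity link), binary (logit) or counts (log); only the mean and
a working covariance are modelled, so inference is semi-parametric and—via
the sandwich variance—asymptotically valid even when the working correlation
is misspecified, provided the mean model is correct.

Each coefficient function is expanded in m B-spline basis functions,
beta_r(s) = sum_d theta_{r,d} B_d(s), giving a coefficient vector theta of
length p = m(q+1). theta solves the penalized estimating equation

    sum_i D_i' V_i^{-1} (Y_i - mu_i) - Lambda S theta = 0,

with D_i = d mu_i / d theta, S the block-diagonal second-order difference
penalty, and Lambda a diagonal matrix holding one smoothing parameter per
coefficient function.

## One-step estimation

Solving the weighted equation directly requires repeated work with the
n_i L x n_i L working covariances. Instead:

1. **Initial fit** theta0: penalized IRLS under working independence
   (V_i = A_i, the variance-function diagonal). This is an ordinary penalized
   function-on-scalar regression; any consistent initial estimate suffices.
2. **One Newton step** with a correlated working covariance:

       theta1 = theta0 + (W_bar + Lambda1 S)^{-1} (b_bar - Lambda1 S theta0),

   where W_bar = N^{-1} sum_i D_i' V_i^{-1} D_i and
   b_bar = N^{-1} sum_i D_i' V_i^{-1} (Y_i - mu_i), all evaluated at theta0.
   For the Gaussian identity model this step is exact (the estimating
   equation is linear); for non-Gaussian families it is asymptotically as
   efficient as the fully iterated fit. The per-cluster summaries W_i, b_i
   are computed once and re-used by the cross-validation, the bootstrap and
   the update itself.

## Working covariance

V_i is block diagonal over grid points, V_i(s) = A_i(s)^{1/2} R_i(s)
A_i(s)^{1/2}. R_i(s) is independence, exchangeable (equal correlation rho(s)
across j), or AR(1) (rho(s)^{|j-j'|}). The exchangeable inverse is applied
through its rank-one closed form in O(n_i); the AR(1) inverse through a
Levinson-type Toeplitz solve, never materializing the matrix. Cross-grid-point
correlation is deliberately not modelled: the simulations show that pointwise
longitudinal correlation already captures most of the attainable efficiency.

rho(s) is estimated at each grid point from Pearson residuals
e_ij(s) = (Y_ij(s) - mu_ij(s)) / sqrt(v(mu_ij(s))): the ordered-pair moment
estimator for the exchangeable structure (divisor n_i (n_i - 1); clusters
with n_i < 2 excluded), and the per-cluster lag-1 Yule-Walker ratio, averaged
over clusters, for AR(1). Estimates are truncated to [-1+eps, 1-eps]
(exchangeable) or [0, 1-eps] (AR1) with eps = 1e-3, and may optionally be
smoothed along s with a centered running mean (window max(5, L/10), off by
default). rho(s) is estimated twice: at theta0 for the update, and again at
theta1 for the variance estimate.

**Dispersion.** Pearson residuals of a Gaussian outcome have variance equal
to the residual variance, not 1, so the raw moment estimator would not be a
correlation. The package estimates a per-point dispersion
phi(s) = mean_ij e_ij(s)^2, standardizes residuals by sqrt(phi(s)) before the
rho estimators, and carries phi(s) into the working variances
(A(s) = phi(s) v(mu)) for the correlated structures. Under working
independence the bare variance function is used, so the initial fit is the
canonical penalized GLM and the GLS-Ind benchmark is plain penalized least
squares. Sandwich inference is insensitive to these weights beyond
efficiency.

**Binomial means** are clamped to [1e-6, 1 - 1e-6] before the variance
function to avoid division blow-ups; the effect vanishes asymptotically.

## Smoothing-parameter selection

* **Lambda0** (initial fit): selected by GCV on the working linearized
  problem, coordinate-wise over a log grid, re-selected within the first IRLS
  iterations and then frozen. (Fast REML would also do; any consistent
  initial fit satisfies the theory. GCV keeps the fit self-contained.)
* **Lambda1** (one-step): fast K-fold cluster cross-validation (default
  K = 10, folds are whole clusters). Fold estimates re-use the full-sample
  initial estimate and the full-sample Hessian factor, with the held-in score
  rescaled by ntilde_k = sum_i n_i / sum_{held-in} n_i, so the entire CV pass
  costs exactly one p x p factorization per candidate (verified by an
  instrumentation counter). The search is two-stage: a shared multiplier c on
  the anchor Lambda0 / (N mean(phi)) over 15 log-spaced points spanning
  1e-4..1e4, then up to two sweeps of 3-point coordinate moves (factor
  10^{+-1/2}) per coefficient. The CV criterion is the held-out negative
  working log-likelihood; ties break toward the smoother candidate. The
  anchor rescaling accounts for the N-normalization and dispersion weighting
  of the one-step equation relative to the initial IRLS; the grid spans eight
  decades, so the anchor only needs to be order-of-magnitude correct.

## Variance estimation and confidence bands

* **Sandwich**: Var(theta1) = N^{-1} H^{-1} M H^{-1} with
  H = W_bar + Lambda1 S and M = N^{-1} sum_i U_i U_i', where
  U_i = D_i' V_i^{-1} (Y_i - mu_i) - Lambda1 S theta1, everything evaluated
  at theta1 with the second-pass rho(s). Curve variances follow by
  congruence with B.
* **Fast cluster bootstrap**: clusters are resampled with replacement; each
  draw re-uses the stored b_i and the single Hessian factor, so a draw is one
  triangular solve. An identity resample reproduces theta1 exactly.
* **Pointwise CIs**: beta_r(s) +/- z_{1-alpha/2} sigma_r(s).
* **Joint bands**: beta_r(s) +/- q_r sigma_r(s), where q_r is the (1-alpha)
  empirical quantile of the max statistic max_s |beta-tilde_r(s)| / sigma_r(s)
  over T draws (default 1000) of theta-tilde_r, either parametric
  N(0, Sigma_r) draws from the sandwich block or centered fast-bootstrap
  draws. Studentization is done in curve space with absolute values, because
  the band is applied in curve space and is two-sided; a theta-space variant
  (max over standardized basis coefficients) is available via
  ``conf_band(space="theta")``. The quantile is floored at z_{1-alpha/2}, so
  joint bands always contain the pointwise CIs; a degenerate (zero)
  covariance block returns the degenerate pointwise interval.

## Synthetic-data designs

The generators are first-class, tested code and define the package's study
conditions.

**Gaussian design** (`gen_sim1`): Y_ij(s) = beta_0(s) + X1_i beta_1(s)
+ X2_ij beta_2(s) + W_ij(s) + eps_ij(s) on L = 100 evenly spaced points in
[0, 1]. X1_i ~ N(0, 1) per cluster; X2_ij = j + e_ij with e an AR(1) of
coefficient 0.7, unit innovation variance and e_i0 = 0. W_ij(s) =
sum_{k=1,2} (xi_ik + zeta_ijk) psi_k(s) with orthonormal psi_1 = 1,
psi_2 = sqrt(2) sin(2 pi s) (the sqrt(2) is the orthonormalizing constant on
[0, 1]) and score variances 3, 2 (cluster level) and 1.5, 1 (observation
level); eps has variance 1.5. All stated magnitudes are variances. The
cluster-level scores make outcomes exchangeable across j at each s (share
(3 + 2 psi_2^2) / (6 + 3 psi_2^2), i.e. 0.5 where psi_2 vanishes) and
correlated across s — so the pointwise working structures are deliberately
misspecified in the functional direction. beta_0 = 3 + sin(pi s)
+ 2 cos(3 pi s); beta_1 = 3 + cos(2 pi s) + 2 cos(3 pi s); beta_2 is a
mixture of standard-normal-density bumps,
(1/60)[phi((s-.2)/.1) + phi((s-.1)/.07)] - (1/200) phi((s-.35)/.1)
- (1/250) phi((s-.65)/.06).

**Binary design** (`gen_sim2`): logit E[Y_ij(s) | X] = beta_0(s)
+ X1_i beta_1(s) + X2_ij beta_2(s) with beta_0 = 1 + sin(pi s)/3
+ (2/3) cos(3 pi s), beta_1 = 1 + cos(2 pi s)/3 + (2/3) cos(3 pi s),
beta_2 = (5/3)[phi((s-.35)/.1) - phi((s-.65)/.2)]. Covariates are drawn as in
the Gaussian design, except X2 is centered and scaled to unit sample variance
before entering the linear predictor — the raw trend j + AR(1) would push
logits to +-25 at n_i = 100 and make the outcome degenerate; this deviation
is flagged in run metadata. Within each (i, s), outcomes are thresholded
uniforms from a latent standard-normal AR(1) Gaussian copula with lag-1
correlation rho across j, independent across s and i. Marginal success
probabilities are exactly expit(eta); the binary-scale lag-1 correlation is
positive and increasing in rho but smaller than the latent rho (tests target
the marginals and the latent mechanism, which are exact).

**What the generators do not emulate**: irregular or sparse grids, missing
functional points, covariate measurement error, non-stationary longitudinal
correlation, or between-cluster heterogeneity in rho. Passing tests therefore
speak to the estimator's behaviour under clean, regular designs with
correctly specified marginal means, not to robustness against mean-model
misspecification.

## Replication studies and their scale

`run_replicates` fits any subset of {one-step, FoSR, GLS-Ind, GLS-Ex, oracle}
to R independently generated datasets (per-replicate seed = base seed +
replicate index; parallel execution would have to preserve that contract) and
reports, per replicate: RMSE = sqrt(mean over all coefficients and grid
points of the squared error), the pointwise 95% CI coverage fraction over
(r, s), and the joint-band full-curve coverage fraction over r. RMSE ratios
against the FoSR reference are means of per-replicate ratios.
`scripts/acceptance.py` runs five study cells at R = 100 replicates each
(N in {25, 50}, n_i in {5, 25}, rho in {0.5, 0.75}), which completes in a few
minutes on one CPU; the package's own tests use R between 15 and 50 for the
paired efficiency comparisons, where the one-step/GLS contrast is strongly
positively correlated across replicates and needs far fewer draws than a
marginal quantity.

## Numerical choices and degenerate inputs

* Cubic B-splines (order 4) with uniform knots and replicated boundary knots;
  m = 13 per coefficient by default (ten knots spanning the domain), with a
  second-order difference penalty (null space: linear trends per
  coefficient). The basis is full rank whenever m <= L.
* IRLS converges at relative change 1e-8 (cap 100 iterations) with
  step-halving on non-finite deviance; complete separation under the binomial
  family is handled by the penalty (finite, strongly negative logits).
* The penalized Hessian is factorized by Cholesky; singularity raises with
  advice to increase smoothing or reduce the basis.
* GLS benchmarks (Gaussian only) alternate the closed-form weighted solve
  with rho re-estimation (tolerance 1e-8, cap 50 iterations, dampened rho on
  detected oscillation) and refresh rho and the cluster summaries at the
  converged estimate before the sandwich.
* All randomness (folds, bootstrap, band draws, generators) flows through
  explicit seeds; there is no wall-clock seeding anywhere.

## Known limitations

* Joint bands are calibrated at the stated level *given* the sandwich
  covariance; in small samples (N ~ 25) the sandwich meat is biased downward
  and penalization bias shifts the band's center, so empirical joint coverage
  can fall below nominal even when pointwise coverage is close to it. The
  quantile floor at z only prevents the band from being narrower than the
  pointwise CI; it does not correct either effect.
* The FoSR benchmark's sandwich aggregates scores at cluster level and is
  therefore robust to within-cluster correlation; it is not a model of
  analyses that treat each longitudinal curve as an independent unit, whose
  coverage degrades sharply as n_i rho grows.
* Regular, evenly spaced grids only; cluster sizes may vary, the grid may
  not.
* The AR(1) structure assumes longitudinal observations equally spaced in
  time.
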