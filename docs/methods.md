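# Methods

## The problem

Permutation variable importance (VIMP) is the standard attribution tool
for random forests: the importance of a feature `X_i` is the increase in
expected loss caused by replacing `X_i` with an independent permuted
copy,

    VIMP(X_i) = E[L(Y, f(pi_i(X)))] - E[L(Y, f(X))],

estimated from out-of-bag (OOB) data.  VIMP measures *marginal*
influence: a feature that carries little information of its own can
still show a large VIMP because it is correlated with strong predictors.
This package quantifies how much of a designated feature's importance is
its own and provides a formal test.

## Residual decomposition and the two models

The feature of interest is renamed `Z` (conventionally the last column,
`Z = X_p`).  A regression model `g` from a model class `G` is fitted by
least squares to explain `Z` from the remaining predictors:

    Z = g(X_{-p}) + eps_Z.

Two forests are then compared:

* **model A** — predictors `(X_{-p}, Z)`; `VIMP_A(Z)` is Z's marginal
  importance;
* **model B** — predictors `(X_{-p}, eps_Z)`; `VIMP_B(eps_Z)` is the
  importance of the part of Z the other predictors cannot explain.

A drop from `VIMP_A(Z)` to `VIMP_B(eps_Z)` means part of Z's importance
is borrowed from correlated predictors; a positive `VIMP_B(eps_Z)` means
Z's own information still helps prediction.

Model classes for `g`: OLS (default, adequate in low dimensions), ridge
(penalised; preferable when p is large, since an overfitted `g` shrinks
the residuals and spuriously deflates `VIMP_B`), or a random forest for
non-linear relations.  For the forest class the training-block residuals
are computed against *OOB* predictions for the same reason; rows that
were never OOB (possible only in very small ensembles) fall back to the
full-forest prediction with a warning.

## The subsampling test

Hypotheses (both one-sided):

    H0(1): VIMP_A(Z) = VIMP_B(eps_Z)   vs.   VIMP_A(Z) > VIMP_B(eps_Z)
    H0(2): VIMP_B(eps_Z) = 0           vs.   VIMP_B(eps_Z) > 0

Procedure, given a learning sample of n rows and `m` subsample draws
(default m = 100):

1. Compute `VIMP_A(Z)` and `VIMP_B(eps_Z)` on all n rows.
2. For b = 1..m: draw `round(0.632 n)` rows *without replacement*
   (ties in the rounding go up); refit `g` on exactly those rows;
   replace Z by the new residuals; train a forest on those rows; record
   the VIMP of the residual column.  Subsampling (rather than a second
   bootstrap layer) keeps training rows out of each tree's OOB set; the
   0.632 fraction matches each row's inclusion probability under a
   size-n bootstrap.
3. Shift the m values so their mean equals the full-sample
   `VIMP_B(eps_Z)` — finite-sample VIMPs are attenuated at subsample
   size, and the mean shift recentres the distribution.
4. Reject H0(1) when `VIMP_A(Z)` strictly exceeds the empirical
   (1 − α)-quantile of the shifted values; reject H0(2) when their
   empirical α-quantile strictly exceeds 0.

Decisions are taken on the *empirical* distribution; kernel densities
appear in plots only.  Quantiles use linear interpolation between order
statistics (the numpy default) — fixed because the rejection boundary
depends on the convention.  Reported p-values use the add-one
permutation convention `(1 + #{d >= VIMP_A}) / (m + 1)` and
`(1 + #{d <= 0}) / (m + 1)`; decisions follow the quantile rule, not a
p-value cut.

Every subsample iteration derives an independent seed branch from the
master seed (numpy `SeedSequence` spawning), so results are independent
of execution order.

## Forest engine

Standard Breiman forests with explicit bookkeeping:

* bootstrap of size `round(fraction * n)` per tree, with replacement by
  default (fraction 1.0); the in-bag multiset and OOB set of every tree
  are retained;
* CART best-split search over `mtry` candidate features per node;
  variance-reduction criterion (for a 0/1 outcome this is exactly the
  Gini criterion, so one kernel serves both tasks); thresholds midway
  between adjacent distinct values; nodes stop at purity or below the
  minimum node size;
* defaults follow the common conventions: 500 trees,
  `mtry = max(floor(p/3), 1)` for regression and `floor(sqrt(p))` for
  classification, minimum terminal node size 5 (regression) / 1
  (classification);
* losses: squared error (regression), 0-1 loss with leaf-majority
  prediction and ties broken toward class 0 (classification);
* VIMP: for each tree the feature is permuted *within that tree's OOB
  rows only*, one permutation per tree by default (`n_perm`
  configurable); per-tree loss differences are averaged over the trees
  that have OOB rows (trees without OOB rows are skipped with a
  warning).  Negative values are reported as-is — truncation would bias
  the subsample distribution.

Tree induction runs in compiled (numba) kernels.  The engine keeps each
feature's in-bag row list sorted by that feature and partitions the
lists stably at every split, so no per-node sorting is needed; bootstrap
duplicates enter as multiplicity counts, which is equivalent to fitting
on the duplicated sample (asserted in the tests).  The split rules
reproduce scikit-learn's `DecisionTreeRegressor` exactly up to the order
in which exactly-tied splits are broken; ties are broken toward the
first candidate in the seeded feature order, making growth
bit-reproducible.  The forest-level permutation importance is
additionally cross-checked against R's independent `ranger`
implementation in the test-suite.

Seeding: one generator per forest (seeded from the forest seed) draws
the bootstrap matrix and one split-search seed per tree in a fixed
order; one generator per (feature, VIMP call) drives the permutation
draws.  The same data, spec and seeds reproduce results bit-identically;
tree fitting is sequential by design, so no parallelism caveats apply.

## Numerical choices

* Residuals whose largest magnitude is below `1e-10 * max(1, max|z|)`
  are snapped to exactly zero: they are float-rounding noise from an
  exactly explained Z, and left alone they would act as a unique row
  fingerprint that trees can memorise, producing a spurious positive
  `VIMP_B`.
* Ridge standardizes features internally (penalty is scale-free) and
  back-transforms coefficients; OLS uses unstandardized least squares
  with an intercept.
* A constant Z is fitted by the intercept alone; a binary Z is rejected
  — the residual decomposition is defined here for continuous Z only.
* `m < 20` is rejected (quantiles unusable), `m < 100` warns;
  `alpha * m < 1` warns that the rejection boundary sits in the tail
  interpolation region.

## Synthetic study designs

Design A (regression):

    Y = b1 X1 + ... + b5 X5 + b6 Z + eps1,  eps1 ~ N(0, sigma1^2)
    Z = 0.5 X1 + 0.5 X2 + eps2,             eps2 ~ N(0, sigma2^2)

with standard-normal X, `corr(X1, X2) = c`, all other correlations zero.
The joint covariance of `(X, Z, Y)` is analytic, so the marginal
correlation `C(Y, Z)` and the semipartial correlation
`spC(Y, Z) = C(Y, eps2)` are closed forms; `solve_sigmas` inverts them
(the spC equation pins Var(Y) as a function of sigma2^2, reducing the
problem to a bracketed one-dimensional root find, solved to ~1e-14 and
validated against 10^6-row Monte-Carlo moments in the tests).

Canonical scenarios:

* *power scenarios*: `b = (0.5, 0.5, 1, 0, 0, 1)`, `c = C(Y, Z)`, noise
  variances solved for targets `(C, spC)` in
  {(0.3, 0.1), (0.3, 0.2), (0.6, 0.2), (0.6, 0.4)}.  For C = 0.9 the
  coefficient configuration cannot attain the target — with
  `sigma1^2 >= 0` the maximum attainable C(Y, Z) is ≈ 0.87 — and the
  solver reports infeasibility rather than clipping silently.
* *null scenario* (spC = 0): `b = (1, 1, 1, 0, 0, 0)`, `c = 0.3`,
  `sigma1^2 = 4.04`, `sigma2^2 = 0.26` (shared with Design B).  Z then
  has no effect of its own (H0(2) true) while remaining correlated with
  Y through X1/X2 (H0(1) false).

Design B (classification) keeps the same feature/Z distribution and
noise variances and draws `Y ~ Bernoulli(inverse-logit(linear predictor
+ eps1))` — note the noise sits inside the link, so even the true model
cannot classify perfectly.  Applying the test to different features
covers all four null/alternative constellations: X1/X2 (both false), X3
(H0(1) true, H0(2) false), X4/X5 (both true), Z (H0(1) false, H0(2)
true).

`run_rejection_study` replays the full test over independently generated
datasets (each (scenario, replication) gets its own seed branch, so
results are chunking-invariant) and reports empirical rejection rates
with binomial standard errors; a JSON-lines checkpoint makes interrupted
studies resumable.

What the generators do *not* emulate: survival outcomes and censoring,
non-Gaussian or high-dimensional feature sets, non-linear relations
between Z and the other predictors, and real-world correlation patterns
beyond a single correlated pair.  Passing the study checks therefore
demonstrates calibration and power of the test machinery under the
stated Gaussian/logistic designs, not performance on arbitrary real
data.

## Problem sizes used in the shipped checks

The full-scale study uses 1000 replications per scenario.  The shipped
checks run at desk scale, chosen once: the acceptance script uses
n = 500, m = 100, 100-tree forests with 100 replications (regression
level check) and 120 replications (classification power check); the
test-suite replays individual cells at 20–50 replications and widens the
full-scale comparison bands by two binomial standard errors at the
replication count used.  Monte-Carlo moment validations use 10^6-row
samples (tolerance ±0.005 ≈ 5 standard errors).

## Known limitations

* The method tests *one* designated feature; joint testing of several
  features and multiplicity control are out of scope.
* The residual decomposition relies on `g` being adequate: an underfit
  `g` (misspecification) underestimates the influence of correlated
  predictors, an overfit `g` deflates residual importance.
  Cross-validated residual extraction is not implemented.
* Survival forests (C-index / weighted losses) are not supported.
* Absolute VIMP magnitudes depend on forest hyperparameters; only the
  comparison and the test decisions are designed to be stable across
  reasonable settings.
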