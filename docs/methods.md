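# Methods

## Model

`kwlpr` estimates a regression function m(x) from descriptors to an
endpoint by fitting, at every query point x0, a polynomial of degree p by
weighted least squares with kernel weights K((x_i − x0)/h). Supported
degrees are p = 0 (local-constant / Nadaraya–Watson, `lc`) and p = 1
(local-linear, `ll`); higher degrees are deliberately outside the surface
because low-order local polynomials extrapolate acceptably while high-order
ones fail badly outside the data range — the wrong trade-off for QSAR use,
where predictions for new compounds routinely sit near or beyond the
training hull. The multivariate p = 1 form uses additive first-order terms
[1, x_i1 − x01, …, x_id − x0d] with no cross terms, the standard
multivariate local-linear design.

Localization uses an independent product kernel with one bandwidth per
descriptor (no off-diagonal bandwidth matrix), and all localization happens
on auto-scaled variables: each descriptor is standardized to zero mean and
unit variance using training-split statistics only (sample, n−1,
denominator), so a fixed bandwidth box is meaningful regardless of the raw
descriptor units and validation rows can never leak into the scaling.
Kernel normalization constants are kept even though they cancel in the
estimator, so printed weights are comparable across implementations.

Both estimators are linear smoothers: the fitted value at any query is
l(x0)ᵀy for a weight vector that depends only on X, the kernel and h. The
package exploits this three ways: predictions are computed from the
smoother matrix in one batched pass; leave-one-out predictions use the
exact rank-one downdate identity ŷ₋ᵢ = (ŷᵢ − Lᵢᵢyᵢ)/(1 − Lᵢᵢ) (with a
literal-refit fallback whenever 1 − Lᵢᵢ < 1e-4, where the division would be
inaccurate — both paths are tested for 1e-10 agreement); and Y-scrambling
reuses one smoother matrix across all permutations, which is algebraically
identical to refitting per permutation because the weights never involve y.

## Numerical choices

* Local solves go through LAPACK (`numpy.linalg.solve`), not the explicit
  inverse of the printed closed form. If a local normal matrix is singular
  (e.g. a one-point neighborhood under p = 1) the solve is retried with a
  trace-scaled ridge, λ = ridge_fallback · tr(A)/m, default
  ridge_fallback = 1e-8; persistent singularity raises a numerical error.
* An empty kernel neighborhood (compact kernel, bandwidth too small) raises
  an explicit error carrying the query rows and advising a larger bandwidth
  or the Gaussian kernel. Inside the LSCV objective the same event instead
  contributes a large finite per-row penalty (1e6 · var(y)) so the
  bandwidth search stays total and is simply pushed away from degenerate h.
* Outlier flags use strict inequalities (leverage > h*, |standardized
  residual| > 3); a compound exactly on a boundary is not flagged.
* PCA component signs are fixed by making each component's
  largest-magnitude loading positive, making loadings and scores
  deterministic and row-order invariant.

## Bandwidth selection

* `cv.ls` minimizes CV(h) = (1/n) Σ (yᵢ − m̂₋ᵢ(xᵢ))², the mean squared
  leave-one-out residual.
* `cv.aic` is the expected Kullback–Leibler criterion concretized as the
  Hurvich–Simonoff–Tsai corrected AIC for linear smoothers,
  AICc(h) = ln σ̂² + (1 + tr(H)/n)/(1 − (tr(H)+2)/n), returning +inf once
  tr(H) + 2 ≥ n — an explicit barrier against the interpolating regime.
* Both are minimized by multistart Nelder-Mead over log-bandwidths inside a
  box, default [0.05, 5] on the scaled scale, 5 restarts (first start at
  the box center, the rest drawn from a generator seeded with the run
  seed), followed by a guard comparison against the box edges. Every
  selection is a pure function of (data, method, bounds, restarts, seed).
* `plugin` is the 1-D direct plug-in rule for local-linear regression:
  ordered blocks are fitted with quartic OLS polynomials (block count
  chosen by Mallows' Cp among 1…max(min(n/20, 5), 1)), giving pilot
  estimates of the curvature functional θ22 = (1/n) Σ m''(xᵢ)² and the
  residual variance σ̂²; these enter
  h = [R(K) σ̂² (b−a) / (n μ2(K)² θ22)]^{1/5}, clipped to the search box.
  Exactly linear data drive θ22 → 0 and h to the upper bound. The
  procedure is deterministic.
* Leave-one-out metrics computed after selection hold the bandwidths fixed
  at their selected values. Re-selecting inside each fold would answer a
  different question (bandwidth stability) at O(n) times the cost.

## Validation panel and conventions

RMSE uses the 1/n denominator in all three variants (calibration,
cross-validation, prediction). Q²_F1 references the validation deviations
from the training mean, Q²_F2 from the validation mean, Q²_F3 compares
per-observation errors against the per-observation training variance. CCC
is Lin's original form with population (1/n) moments. Reports display at 2
decimals; full precision is kept internally. An empty validation split
yields absent (None) external metrics, never zeros.

Y-scrambling permutes training responses only, keeps descriptors and
bandwidths fixed, and records R² (and Q²_LOO) per permutation; permutation
k uses `default_rng([seed, k])`, a counter scheme independent of execution
order, and the identity permutation can be injected as permutation 0. The
summary statistic is the empirical p-value: the fraction of permutations
whose R² reaches the true model's. Bandwidths are not re-selected per
permutation — that would multiply cost by the permutation count and mix
selection variability into the null distribution.

The applicability domain is assessed on the global auto-scaled design with
intercept, the classical (model-agnostic) Williams-plot convention, with
h* = 3(d+1)/n_train: for two descriptors and 254 training compounds this
gives 9/254 ≈ 0.035. Validation rows are scored against the training
normal matrix, so the domain of a new compound is assessable before
prediction.

## Synthetic fixtures: what they emulate and what they do not

The generators produce tables in the same CSV layout as real modeling
inputs, with ground truth returned alongside:

* `sine1d` — one uniform descriptor on [0, 2π], truth sin(x), Gaussian
  noise; the default noise sd (≈0.236) sets the signal-to-noise ratio to
  3:1, a regime where smoothing visibly matters but the signal is
  recoverable.
* `linear1d` — exact affine truth 2x + 1 (noise defaults to 0); the
  polynomial-reproduction fixture.
* `qsaar2d` — two correlated Gaussian descriptors (correlation 0.5,
  matching the moderate interspecies correlations typical of such tables;
  means/sds 2.5/1.5 and 1.5/1.2, plausible LogP-like and pEC50-like
  scales), response 0.27 + 0.17·x1 + 0.67·x2 + 1.2·tanh(x1 − 2.5) plus
  noise sd 0.6. The tanh term makes the truth genuinely nonlinear in the
  lipophilicity-like descriptor — a saturating potency dependence — so a
  local estimator has something to gain over a global plane, while the
  linear backbone keeps the response range and error magnitudes (~0.6 log
  units) in the regime of real interspecies toxicity models. Default
  sample sizes 254/64 mirror a large pesticide-scale study.
* `noise_only` — response independent of the descriptor; the null fixture
  for Y-scrambling calibration.

These fixtures deliberately omit features of real descriptor tables:
heavy-tailed and discrete (count) descriptors, measurement error in the
predictor endpoint of a QSAAR, activity cliffs, and cluster structure from
congeneric series. Passing tests therefore demonstrate correctness of the
estimator, selectors, metrics and workflows under smooth truths with
Gaussian noise — not that KwLPR will outperform a global model on any
particular real dataset. Replication against published case-study tables
requires the user to supply those tables (`--fix-bandwidth` pins the
printed per-descriptor bandwidths; whether printed bandwidths live on the
raw or auto-scaled variable scale is ambiguous in such reports — this
package fixes its own bandwidths to the scaled scale, and a replication
should try both readings before concluding a mismatch).

## Problem sizes

The test suite and the acceptance script run entirely on the synthetic
fixtures at the sizes named above (largest: 254 training / 64 validation
rows, 2 descriptors; 100 Y-scrambling permutations; 200-instance oracle
sweeps), chosen so the whole suite completes in seconds while still
exercising every code path at realistic QSAR dimensions.

## Known limitations

* No adaptive/variable bandwidth h(x); constant bandwidth only.
* Degrees above 1, derivative estimation and confidence bands are out of
  scope.
* The direct plug-in selector is restricted to one descriptor with the
  local-linear estimator (its multivariate generalization is not
  standardized); `cv.ls`/`cv.aic` cover the general case.
* Descriptor calculation from structures is out of scope: inputs are
  numeric tables.
* The AICc and LSCV objectives can be multimodal in h; the multistart
  search mitigates but cannot guarantee the global minimum, which is why
  selections are seeded and reported with their objective value.
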