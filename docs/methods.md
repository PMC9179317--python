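# Methods

## Risk model and conditional likelihood

For subject `i` in matched set `j` of study `s`, with case indicator
`Y`, reference-scale biomarker `X` and confounders `Z`:

    logit P(Y = 1 | X, Z) = beta_0sj + beta_X' f(X) + beta_Z' Z.

`f` is a restricted cubic spline basis with knots `t_1 < ... < t_K`:
`f_1(x) = x` and, for `k = 1, ..., K-2`,

    f_{k+1}(x) = (x - t_k)+^3
               - (x - t_{K-1})+^3 (t_K - t_k)/(t_K - t_{K-1})
               + (x - t_K)+^3 (t_{K-1} - t_k)/(t_K - t_{K-1}).

Each nonlinear component is identically zero below its knot and linear
above `t_K`, and the basis is C² everywhere. No rescaling of the
nonlinear columns is applied by default (a `normalize` flag divides by
`(t_K - t_1)^2` for users who want scale-free columns); this keeps the
coefficients on the same scale as the unscaled textbook formula.
`K = 3` is the default; `K` from 3 to 7 is supported. When knots are
placed from data, empirical quantiles use the median-unbiased
convention; the fit is far more sensitive to the *number* of knots than
to their exact placement, so the quantile convention is a second-order
choice.

Conditioning each matched set on its number of cases `n_sj` eliminates
`beta_0sj`. The conditional likelihood of the observed case set is
`1 / (1 + sum_k exp(eta_k))`, the sum running over all other subsets of
size `n_sj`, where `eta_k` is the inner product of `beta` with the
difference between the subset's summed design rows and the observed
cases' summed rows. Only within-stratum differences enter, so any
constant shift of `f(X)` or `Z` within a stratum cancels — this is what
makes the full-calibration method robust to the controls-only intercept
bias (below).

Implementation: the map from subject design rows to subset-difference
rows is materialized once as a sparse matrix (one row per non-case
subset: +1 on subset members, −1 on cases), after which the pooled
log-likelihood, score, Hessian, per-stratum score contributions and all
chain-rule derivatives are dense vectorized segment operations. For 1:1
pairs this is a single row per stratum. General `n:m` sets are
enumerated exactly, guarded at `n + m <= 20` and `C(n+m, n) <= 1e6`;
larger sets raise an error rather than silently approximating, since
matched sets in pooling projects are small.

## Calibration and imputation

Local-laboratory measurements `W` are mapped to the reference scale via
a per-study line `E(X | W, control) = a_s,co + b_s,co W`, estimated by
OLS among the study's re-assayed controls (cases are rarely re-assayed;
a case in the calibration subset is rejected loudly rather than used).
Matching factors or nonlinear transforms of `W` may be added as extra
columns. Controls-only estimation biases the intercept slightly when
the biomarker affects risk; under **full calibration** (impute
`a + bW` for *every* subject of the study) that bias is common to the
whole stratum and cancels in the conditional likelihood, which is why
full calibration is the recommended default. Under **internalized
calibration** (use observed `X` when present) the cancellation is
incomplete, and its residual bias grows with the calibration
proportion. The **naive** method (fit `W` directly) is retained as a
negative control.

## Two-step estimation and variance

Step 1 estimates `(a_s, b_s)` per study; step 2 maximizes the pooled
approximate conditional log-likelihood in `beta` by Newton–Raphson with
analytic score and Hessian (start `beta = 0`, convergence when
`max |score| <= 1e-8`, at most 100 iterations, step-halving on any
likelihood decrease). The conditional log-likelihood is concave, so
Newton steps on the observed information are stable; perfect separation
is detected when the achieved likelihood is within `1e-8 * J` of its
upper bound of 1 and raises an explicit error.

Variance: stack the estimating functions
`psi = (psi_a, psi_b per calibrated study, psi_beta)` by stratum — the
OLS normal-equation scores of each stratum's re-assayed controls
together with the stratum's likelihood score — and use the M-estimation
sandwich `A^{-1} B A^{-T}` with `A = -sum_j d psi_j / d theta'`,
`B = sum_j psi_j psi_j'`. Strata are independent by design; keeping a
calibration subject's OLS score in the same unit as its stratum's
likelihood score preserves their correlation. `A` is block-triangular:
the calibration block is the OLS Gram matrix, the `beta` block is the
observed information, and the cross block `d psi_beta / d (a_s, b_s)`
is computed analytically by the chain rule through
`X~ = a_s + b_s W` and the spline derivative `f'(X~)`. A
central-difference mode (`h = 1e-6 (1 + |theta|)`) is available and
tested against the analytic bread. For the naive method (or data
entirely on the reference scale) the stacked system contains no
calibration parameters and reduces to the usual robust
conditional-logistic variance. Model-based standard errors (inverse
observed information) are also reported but intervals and Wald tests
default to the sandwich.

Wald tests use the sandwich covariance; the no-nonlinearity test is the
joint test that all nonlinear spline coefficients vanish. Dose–response
curves report `beta_X'(f(x) - f(x_ref))` with *pointwise* normal 95%
bands from the `beta_X` sandwich block (no simultaneous-band procedure
is attempted). The reference level defaults to the minimum of the
curve grid, matching the common convention of anchoring at the lowest
observed biomarker value. Note that `f(x_ref)` includes the nonlinear
components: with knots at the N(0,1) quartiles, `f_2(0) = (0-t_1)^3 > 0`,
so the curve through `x_ref = 0` is not simply `beta_X' f(x)`.

## Synthetic-data generator

The generator emulates a pooling project in which **every** study uses
a local laboratory. Per study, `(X, W)` are jointly Gaussian with
`E(X) = mu_x`, `Var(X) = sigma2_x`, `E(W) = (mu_x - a_s)/b_s`,
`Var(W) = sigma2_w[s]` and `Cov(X, W) = b_s sigma2_w[s]`, which yields
exactly `E(X | W) = a_s + b_s W` with residual variance
`sigma2_x - b_s^2 sigma2_w[s]` (validity requires that this is
non-negative, enforced at configuration time). Per stratum, a random
intercept `beta0 ~ N(0, 0.01)` is drawn — the small variance keeps case
and control probabilities near 1/2 so stratum generation is cheap —
candidates are drawn with `Y ~ Bernoulli(expit(beta0 + beta_X' f(X)))`
until the stratum holds at least one case and one control, and one of
each is chosen uniformly at random (candidates are i.i.d., so the
selected case and control are draws from the case and control
conditional distributions). Candidate draws are capped at 1e5 per
stratum, with an error naming the stratum, to flag pathological
configurations. The calibration subset is a simple random sample of
each study's controls of size `round(proportion x controls)`, floored
at 3 (the decile-stratified sampling used in some applied projects can
be emulated by flagging rows externally).

Default scenario: 4 studies x 500 pairs, `mu_x = 0`, `sigma2_x = 1`,
`a = (-3, 1, -1, 3)`, `b = (0.5, 0.75, 1.25, 1.5)`,
`sigma2_w = (3.8, 1.7, 0.6, 0.4)` (so the calibration lines explain
90–96% of `Var(X)` across studies), knots fixed at the N(0,1)
quartiles `(-0.6745, 0, 0.6745)` for all three methods so their
estimates are comparable, and `beta_x = (-log 1.25, 0.08)`. Replicate
`r` of a simulation uses the `r`-th spawned child of the master seed,
so runs are reproducible and replicates independent. Relative bias is
the mean over replicates of `(betahat - beta)/beta` (in percent);
coverage is the fraction of replicates whose 95% sandwich Wald interval
contains the truth; non-converged fits are excluded from summaries and
counted separately.

What the generator does *not* emulate: non-Gaussian biomarker
distributions, `n:m` matched sets (the fitter handles them; the
generator is 1:1), laboratory drift within a study, covariates in the
risk model, and calibration-subset sampling that depends on the
biomarker level. Passing simulation tests therefore show correctness of
the estimator under the stated Gaussian measurement structure, not
robustness to violations of it.

## Numerical and design choices

- Per-stratum log-sum-exp is anchored at `max(0, max eta)`, so the
  implicit `exp(0)` term of the observed case set never overflows.
- Singular bread matrices fail loudly with the condition number
  (threshold 1e12).
- A study whose subjects were all re-assayed is still imputed under
  full calibration — the rule is applied regardless of `X`
  availability.
- Laboratory status is study-level: a study is treated as
  reference-laboratory when every subject has a reference value and no
  calibration flags are set (an explicit `reference_studies` override
  exists for ambiguous files).
- Missing reference values are empty fields in the delimited format;
  the case column must be exactly 0/1.
- The surrogacy assumption (given `X`, the local value `W` carries no
  extra outcome information) and the linearity of `E(X | W)` are
  assumptions of the method, not runtime checks; no diagnostic for the
  Taylor-approximation error is attempted.

## Problem sizes

The bundled experiments use the default scenario at 1000 replicates in
`scripts/acceptance.py` (a few minutes on one CPU: each replicate is
2000 strata generated and fitted in ~25 ms) and reduced replicate
counts (120–1000) in the test suite, with tolerances widened by the
implied Monte-Carlo standard errors.

## Known limitations

- The internalized method's bias at high calibration proportions is
  reproduced qualitatively but is sensitive to fine details of how the
  calibration subset is drawn.
- No bootstrap or likelihood-ratio inference (the latter is invalid
  under pseudo-likelihood without adjustment).
- Calibration across more than two laboratory tiers and
  errors-in-both-variables (Deming) calibration are out of scope.
- The sandwich with extra calibration covariates (matching factors) is
  not implemented; point estimation supports them.
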