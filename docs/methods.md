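# Methods

This note documents the statistical models implemented in `betaridge`, the
conventions chosen where several are in circulation, the synthetic-data
generators and what they do and do not emulate, and the numerical details
that matter for reproducing results.

## Models

### Linear model and ridge regression

OLS is fitted by QR through `statsmodels`; the stored log-likelihood is the
gaussian likelihood at the ML variance `RSS/n`, and the parameter count is
`p + 2` (coefficients, intercept, residual variance), so AIC/BIC across
models use a single convention.

Ridge regression works on the correlation scale: each predictor is centered
and divided by the root of its centered sum of squares ("unit-length"
scaling), so the cross-product of the standardized design is the
correlation matrix and the ridge constant `k` is commensurate with its unit
eigenvalue scale. The response is centered but not scaled; the
Hoerl–Kennard rule `k = p σ̂² / β̂'β̂` is invariant to the response's units
because numerator and denominator scale together. Raw-scale coefficients
and intercept are recovered exactly from the centering/scaling vectors.
Standard errors on the standardized scale use the sandwich form
`σ̂² (S+kI)⁻¹ S (S+kI)⁻¹` of the linear shrinkage estimator, with
`σ̂² = RSS(k)/(n−p−1)`. A z-score standardization is available as an
option; the unit-length form is the default because ridge theory (the
canonical MSE decomposition, the HK rule) is stated in it.

The canonical-coordinate MSE uses `k²` in the bias numerator,
`Σ (λᵢσ² + k²αᵢ²)/(λᵢ+k)²`: this is the form whose `k → ∞` limit equals
the total squared signal `Σ αᵢ²`, as shrinkage to zero requires, and it is
verified against a 200 000-draw Monte-Carlo estimate of
`E‖β̂(k) − β‖²` in the test suite.

The ridge fit's likelihood for model selection is the gaussian likelihood
at the ridge fitted values; the ridge constant is not counted as a free
parameter (it is either fixed a priori or a deterministic function of the
data through the HK rule), so `k_params = p + 2` as for OLS.

### Beta regression

The response lies strictly inside (0, 1) and follows the mean/precision
beta law with shapes `(μφ, (1−μ)φ)`, so `E(y) = μ` and
`var(y) = μ(1−μ)/(1+φ)`; the mean is logit-linked. The likelihood is
maximized jointly in `(β, log φ)` by L-BFGS-B with the analytic score,
then polished by Fisher scoring in `(β, φ)` until the score is negligible.
Initialization: `β` from OLS of `logit(y)` on the design; `φ` from the
method-of-moments relation `μ̄(1−μ̄)/v̄ − 1` with `v̄` the fitted-scale
residual variance.

Convergence is declared when the score's largest entry falls below `1e-6`,
or below `1e-8` after rescaling each component by the root of its Fisher
information diagonal. The second, scale-invariant criterion matters for
data with large covariate or precision scales (on the reference table
`φ̂ ≈ 3.8e4` and area spans hundreds of square pixels; the raw score's
attainable floor is then set by floating-point cancellation, not by the
optimizer). Standard errors come from the inverse expected information,
whose `(β, φ)` blocks are available in closed form via trigamma functions.

`working_weights` returns the Fisher-information weights of the mean
submodel, `wᵢ = φ²[ψ′(μᵢφ) + ψ′((1−μᵢ)φ)](μᵢ(1−μᵢ))²`, so that
`X'WX` *is* the expected information for `β` at fixed `φ`. (Some authors
factor one power of φ out of W and write the information as `φX'WX`; the
two conventions describe the same matrix.) Observed and expected
information differ by a term proportional to `(y* − μ*)(1−2μ)` that
vanishes identically when every `μᵢ = 1/2` — the configuration used for the
tight finite-difference oracle test — and is `O(n^{-1/2})` relative at a
generic ML fit.

### Beta ridge regression

The ML coefficients are shrunk through the information geometry:
`β̂_BRR = (A + kI)⁻¹ A β̂_ML` with `A = X'ŴX` evaluated at the ML fit.
This is the unique minimizer of the Lagrangian
`β'β + (1/k)[(β−β̂_ML)'A(β−β̂_ML) − Θ₀]`, i.e. the shortest coefficient
vector among those whose weighted distance from the ML solution is fixed —
the Hoerl–Kennard construction transplanted to the weighted geometry. The
precision is held at `φ̂_ML` (only `β` is shrunk), and the reported
log-likelihood is evaluated at `(β̂_BRR, φ̂_ML)`. The working-response
decomposition `Θ(β) = Θ_min + (β−β̂_ML)'A(β−β̂_ML)` is reported with
`Θ_min = (z−η̂)'Ŵ(z−η̂)` for the IRLS working response `z`. Besides a
user-fixed `k`, a Hoerl–Kennard analogue `k = (p+1)/β̂_ML'β̂_ML` (unit
dispersion on the link scale) is provided; a fixed, user-supplied `k` is
the default because no data-driven choice is canonical for this estimator.

### Deviance residuals

The per-record deviance contribution compares the fitted likelihood with
the record's *maximized* likelihood over the mean. For the beta law that
maximum is **not** at `μ = y`: it solves
`ψ(μφ) − ψ((1−μ)φ) = logit(y)`, and evaluating the "saturated" term at
`μ = y` instead produces genuinely negative contributions (observed at the
order of 1e-3 for moderate φ). The saturated mean is therefore computed
per record by a vectorized, monotone Newton iteration on the logit scale;
contributions are then provably non-negative, the residuals satisfy
`Σ rᵢ² = deviance` exactly, and the sign convention is `sign(y − μ̂)`.

### GAMs with penalized regression splines

Smooths use cubic regression splines in the value-at-knot
parameterization: knots at evenly spaced quantiles of the distinct
covariate values, the exact integrated-squared-second-derivative penalty
`D'B⁻¹D` (rank `k−2`, null space = straight lines), natural boundary
conditions with linear extrapolation beyond the knot range (flagged by a
warning). Each smooth carries a sum-to-zero constraint over the training
data, absorbed by a QR reparameterization that drops one column.

Fitting is penalized IRLS in the coefficients at fixed smoothing, with the
penalized log-likelihood monitored and step-halved so it never decreases.
For the beta family the precision is updated by guarded Newton steps on
its profile score inside the alternation and polished to convergence at
the end. Smoothing parameters (one per smooth) minimize the gaussian REML
criterion, or its Laplace-approximate marginal-likelihood extension for
the beta family, over `log λ`: a cheap one-dimensional search for a shared
smoothing level first, then a short Nelder–Mead refinement per term, with
`log λ` bounded in `[−18, 18]` to keep the penalized normal equations in a
numerically representable range. The two-stage search trades a small
amount of per-term optimality for a large constant factor in the
Monte-Carlo study; the reported criteria are insensitive to the residual
λ imprecision because the criterion surface is flat at its minimum.

Effective degrees of freedom are
`τ = tr[(X'WX + Σλⱼ Sⱼ)⁻¹ X'WX]` with the family working weights at
convergence (identity for gaussian); per-term values come from the
corresponding diagonal blocks. A specification with no smooth terms
reduces exactly to OLS (gaussian) or to the beta ML fit (beta family), by
construction rather than by numerical accident. The conditional AIC of a
penalized fit is `−2ℓ + 2(τ + 1)`, with `ℓ` the unpenalized log-likelihood
at the penalized estimate and the `+1` for the scale/precision parameter.

## Diagnostics conventions

VIF is `1/(1−R²ⱼ)` from regressing predictor j on the rest plus intercept;
exactly collinear columns report infinity. The condition number is
`√(λ_max/λ_min)` and is convention-sensitive; two conventions are
implemented:

* `design` (default): the intercept-augmented design with every column
  scaled to unit length — the Belsley collinearity-diagnostics convention.
  This is the convention under which the published value for the
  diagnostic table (166.861) is reproduced, with the diagnosis indicator
  coded benign = 1 / malignant = 0 as in that published computation.
* `correlation`: eigenvalues of the predictor correlation matrix (gives
  27.6 on the same table).

The diagnosis label is otherwise coded B = 0, M = 1 throughout, so a
positive diagnosis coefficient reads "malignancy raises the response".

## Response scaling for the beta family

The beta models need the response inside (0, 1); `prepare_beta_response`
divides by a user scale that must exceed the maximum. The default scale of
100 for the radius response makes the published beta and linear
coefficient magnitudes mutually consistent (a perimeter coefficient near
`1.56e-3` on the scaled response corresponds to radius ≈ perimeter/(2π)).
Information criteria are scale-dependent through the Jacobian
(`n ln 100` in log-likelihood), so published AIC/BIC values for this table
correspond to the scaled response; R², F and t/z statistics are
scale-invariant.

## Synthetic data

Two generators define the study conditions.

**Monte-Carlo cells.** Four predictors from a zero-mean multivariate
normal with exchangeable correlation ρ (closed-form eigenvalues `1−ρ` and
`1+3ρ` make positive-definiteness explicit) and optional diagonal scaling
D (default identity). The response is beta with precision φ = 15 and
logit-linear mean with intercept 3 and slopes (0.5, 0.5, 0.5, 0.5). The
intercept pushes many means close to 1, where one beta shape drops below
one and draws can underflow to the representable boundary; such draws are
redrawn and, if the boundary distance itself underflows double precision,
nudged to the nearest interior value (1e-12). Default replication count is
1000; the acceptance checks run the full (n, ρ, k) grid at 100
replications, a size chosen so the whole directional study completes in
about a minute while leaving every directional conclusion stable across
reruns (cell standard errors are reported alongside the means).

Replicate seeds derive from (master seed, n, 1000ρ, replicate counter)
through `numpy`'s `SeedSequence`, deliberately excluding the ridge
constant: the same datasets are reused across the k grid, making the
GAM/beta/GAM-beta criteria *exactly* invariant to k, and the whole sweep is
a pure function of the master seed.

In the simulation the gaussian GAM smooths all four predictors with basis
dimension 6 (small because p = 4 and n runs down to 25); the GAM-beta
model enters its terms parametrically — the same replication default as
the real-data pipeline, where the published beta and GAM-beta coefficient
tables are essentially identical. With smooths on the beta GAM instead,
smoothing selection shrinks to the (true) linear predictor and the
effective parameter count drops below the parametric beta model's, which
reverses the fine ordering of those two rows; the parametric convention is
documented here precisely because the choice is consequential at the
third significant digit of the criteria.

**Diagnostic-table emulator.** A ten-dimensional gaussian copy of the
published correlation matrix (repaired to positive definiteness by
eigenvalue clipping at 1e-6 and diagonal renormalization; the repair stays
within Frobenius distance 0.05 of the printed matrix) drives nine
continuous features rescaled to the published means/SDs, a probit-threshold
diagnosis indicator at 37.3% malignancy whose latent coordinate carries
the published diagnosis correlations, and a radius response equal to
perimeter/(2π) plus gaussian noise with σ = 0.1 — reproducing the
perimeter/area/radius near-collinearity (VIF far above 5) that motivates
shrinkage. The emulator matches first and second moments only: it does not
reproduce the real table's skewness, strictly positive supports (extreme
draws of small-mean features can be negative), or any higher-order
structure, so tests that pass on it certify the estimators' behaviour
under the published correlation regime, not on real cytology data. Rows
whose perimeter draw would be non-positive (vanishingly rare) are redrawn
so the derived radius stays positive for unit-interval rescaling.

## Numerical choices

* Least-squares subproblems use QR/`lstsq` or Cholesky-backed `solve`;
  no explicit inverses on the solution path (inverses appear only in
  closed-form covariance formulas).
* Inverse-logit means are clipped to `[1e-12, 1−1e-12]` inside likelihood
  and IRLS internals so that transient optimizer iterates with extreme
  linear predictors stay finite; converged fits are interior and
  unaffected.
* Beta ML convergence: absolute score < 1e-6 or information-scaled score
  < 1e-8; a fit is reported non-converged below a scaled score of 1e-3 and
  raises (with the iteration trajectory attached) beyond it.
* P-IRLS inner tolerance 1e-8 relative on the penalized log-likelihood;
  step halving guarantees monotone ascent.
* Ties in model comparison break toward fewer parameters, then label
  order, so reports are reproducible.
* CSV round-trips use shortest-repr floats on write and round-trip float
  parsing on read, so a written `Dataset` reloads bit-identically.

## Known limitations

* Constant precision φ only; no variable-dispersion beta regression and no
  zero/one-inflated variants.
* Smooths are univariate cubic regression splines; no tensor products,
  random effects, or AIC corrections for smoothing-parameter uncertainty.
* Ridge k-selection is restricted to fixed values and the Hoerl–Kennard
  rule; no generalized cross-validation.
* The gaussian-likelihood AIC of ridge/OLS and the beta-likelihood AIC of
  the unit-interval models compare likelihoods for the same numbers under
  different reference measures; when the response is genuinely
  beta-distributed the beta models dominate this comparison, and the
  package reports exactly that.
* The beta-ridge criterion inherits the ML precision; for very large k its
  likelihood is evaluated far from the ML coefficients, where holding φ
  fixed is a rough approximation.
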