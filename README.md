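# betaridge

Regression model comparison for collinear biomedical data: ordinary least
squares, Hoerl–Kennard ridge regression, beta regression by maximum
likelihood, beta ridge regression, and penalized-spline GAMs for gaussian
and unit-interval responses — together with multicollinearity diagnostics
(correlation screen, VIF, condition number), AIC/BIC model selection, and a
replicated Monte-Carlo study of estimator performance.

## Who this is for

Biostatisticians modelling a continuous clinical outcome from strongly
correlated morphology features — the motivating case is the Breast Cancer
Wisconsin Diagnostic table, where tumour radius is regressed on diagnosis
plus nine cytology features and perimeter/area are nearly collinear
(VIF ≈ 80 and 57). The package makes the standard remedies comparable on a
single footing.

## The models

With response $y$ and design $X$ ($n \times p$, intercept added at fit
time):

* **OLS** — $\hat\beta = (X'X)^{-1}X'y$, solved by QR.
* **Ridge** — on centered, unit-length-scaled predictors (so $S = Z'Z$ is
  the correlation matrix), $\hat\beta(k) = (S + kI)^{-1}Z'y$. The biasing
  constant is user-fixed or chosen by the Hoerl–Kennard rule
  $k = p\hat\sigma^2/\hat\beta'\hat\beta$. The canonical-coordinate mean
  squared error $\sum_i (\lambda_i\sigma^2 + k^2\alpha_i^2)/(\lambda_i+k)^2$
  is available for bias/variance analysis.
* **Beta regression** — $y_i \in (0,1)$,
  $y_i \sim \mathrm{Beta}(\mu_i\phi, (1-\mu_i)\phi)$ with
  $\operatorname{logit}(\mu_i) = x_i'\beta$ and precision $\phi$; fitted by
  quasi-Newton plus Fisher scoring on the joint $(\beta, \phi)$ likelihood,
  with standard errors from the expected information.
* **Beta ridge** — shrinkage through the information geometry,
  $\hat\beta_{BRR} = (X'WX + kI)^{-1} X'WX\, \hat\beta_{ML}$, with $W$ the
  Fisher working-weight matrix of the logit-link beta model at the ML fit.
* **GAM / GAM-beta** — $\eta_i = \beta_0 + \sum_j f_j(x_{ij})$ with cubic
  regression splines, exact second-derivative penalties and sum-to-zero
  constraints; coefficients by penalized IRLS, smoothing parameters by REML
  (gaussian) or Laplace-approximate marginal likelihood (beta); model size
  measured by effective degrees of freedom.

Model comparison uses $\mathrm{AIC} = -2\ln L + 2k$ and
$\mathrm{BIC} = -2\ln L + k\ln n$, with $k$ the parameter count
(coefficients + scale/precision; the effective degrees of freedom plus one
for penalized fits, i.e. the conditional-AIC convention).

## Worked example

```python
import betaridge as br

# bundled 569-record diagnostic table (distributed with scikit-learn)
data = br.load_reference_table()                    # radius_mean response
unit = br.load_reference_table(beta_scale=100.0)    # response / 100, in (0,1)

rep = br.diagnose(data)
print("VIF perimeter: %.3f" % rep.vif["perimeter_mean"])

beta = br.fit_beta_ml(unit)
print("beta intercept: %.3f  perimeter: %.4e (z = %.3f)"
      % (beta.params["const"], beta.params["perimeter_mean"],
         beta.zvalues["perimeter_mean"]))

ridge = br.fit_ridge(data, k_policy="hoerl_kennard")
print("HK ridge k: %.3e  dominant SC coefficient: %s"
      % (ridge.k, ridge.params_sc.abs().idxmax()))
```

prints

```
VIF perimeter: 80.084
beta intercept: -3.290  perimeter: 2.0859e-02 (z = 91.609)
HK ridge k: 9.383e-06  dominant SC coefficient: perimeter_mean
```

The VIF of 80 confirms severe collinearity (anything above 5 is flagged);
the beta fit says a one-unit increase in perimeter multiplies the odds-scale
mean tumour radius by about `exp(0.0209)`, overwhelmingly significant; the
Hoerl–Kennard constant is tiny here because the fit is extremely strong
(R² ≈ 0.9994), so almost no shrinkage is warranted on these data. An
AIC/BIC table across any set of fitted models comes from
`br.compare_models({...}, n=data.n)`.

## Command line

```sh
betaridge synth --n 569 --seed 1 --out table.csv       # emulated table
betaridge diagnose --input table.csv --response radius
betaridge fit --input table.csv --response radius --model ridge --k auto
betaridge analyze --config run.yaml --seed 1           # full pipeline
betaridge simulate --config sim.yaml --out sim_out     # Monte-Carlo sweep
```

The Monte-Carlo sweep draws four multivariate-normal predictors with
exchangeable correlation ρ ∈ {0.7, 0.8, 0.9}, a beta response with φ = 15,
fits all five models per replicate, and reports mean AIC/BIC per
(n, ρ, ridge-k) cell; within a cell the same datasets are reused across the
k grid, so the non-ridge rows are exactly invariant to k.

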