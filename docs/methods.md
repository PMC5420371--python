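# Methods

This note records the statistical model, the estimation choices, the
defaults, and the limitations of the `semdif` package. Field-standard
vocabulary is used throughout; see the README for usage.

## Problem

A questionnaire scale of ordinal items is *measurement-invariant* (free of
item bias / differential item functioning, DIF) when the distribution of
an item response given the latent trait does not depend on group
membership or other respondent characteristics ("violators", e.g. gender
or age). Biased items distort group comparisons: part of an observed
group difference in scale scores is caused by the items, not the trait.
`semdif` detects biased items, quantifies the bias, and re-estimates the
group difference or trait-violator association with the bias taken into
account.

## Measurement model

Each ordinal item \(x_i\) (K categories) is a discretized latent normal
response \(y_i\): \(x_i = k \iff \tau_{i,k-1} < y_i \le \tau_{i,k}\) with
thresholds \(\tau_i\). The \(y_i\) follow a common factor model

\(y_i = \nu_i + \lambda_i \xi_{f(i)} + \varepsilon_i\)

with loadings \(\lambda\), intercepts \(\nu\), one or two correlated
factors \(\xi\), and unique variances \(\theta\). Estimation is in the
correlation metric: in the reference group (or the single group) the
underlying variables are standardized, so \(\theta_i = 1-\lambda_i^2\)
(one group/factor) is determined rather than free.

## Stage 1: thresholds and polychoric/polyserial correlations

* **Single-group design**: thresholds are normal quantiles of cumulative
  category proportions. Empty extreme categories are collapsed; interior
  empty categories get a 0.5 pseudo-count.
* **Two-group design**: thresholds are constrained equal across groups;
  the reference group's underlying variable is fixed to N(0,1) and the
  focal group's mean and SD are free. All three are estimated jointly by
  maximum likelihood from the two groups' univariate margins
  (`joint_margin_ml`). With only 2 observed categories the focal SD is
  not identified and is fixed at 1.
* **Correlations**: polychoric (item-item) by two-step ML with thresholds
  fixed — a bounded 1-D likelihood optimization using an own
  implementation of the bivariate normal CDF (Gauss-Legendre quadrature
  on the Drezner-Wesolowsky representation, verified to ~1e-15 against
  an independent quadrature oracle); polyserial (item-covariate) by
  two-step ML with the covariate standardized; product-moment among
  covariates.
* **Bivariate-normality diagnostic**: per item pair, the RMSEA of the
  fitted bivariate normal table; pairs above 0.1 are flagged in reports.
* **Asymptotic covariance** \(\Gamma\) of the stacked moment vector
  (correlations; plus focal means/SDs in the two-group design) is
  assembled from per-observation influence functions, propagating the
  threshold (and focal mean/SD) estimation error into every correlation
  via the implicit function theorem. A seeded nonparametric within-group
  bootstrap (`bootstrap_acov`) is provided as an independent
  cross-check; IF and bootstrap diagonal SDs agree to a few percent at
  n=800/group.

## Stage 2: DWLS fitting and fit statistics

Models are fitted by diagonally weighted least squares: minimize
\((s-\sigma(\theta))' \mathrm{diag}(\Gamma)^{-1} (s-\sigma(\theta))\)
with a trust-region-reflective Gauss-Newton (bounded). Robust standard
errors use the sandwich formula with the full \(\Gamma\).

* **Chi-square**: the residual-based WLS statistic
  \(T=(N-1)\,d'[\Gamma^{-1}-\Gamma^{-1}\Delta(\Delta'\Gamma^{-1}\Delta)^{-1}\Delta'\Gamma^{-1}]d\),
  which is asymptotically \(\chi^2_{df}\) at any consistent estimator
  (including the DWLS solution). The naive quadratic form
  \((N-1)d'\Gamma^{-1}d\) is *not* chi-square distributed at DWLS
  estimates and is not used. Null simulations: mean chi-square 28.6 at
  df 28, 41.2 at df 40; difference 12.6 at df 12.
* **df accounting**: formal moments per group are p means + p(p+1)/2
  (co)variances; \(\nu,\theta\) count per group; reference factor mean 0
  and variance 1 fixed. This equals the effective count (stochastic
  moments minus free parameters) under the correlation-metric
  identification, and reproduces 28/40/38/37/34 (two-group) and
  76/100/88 (one-group) for the standard configurations.
* **RMSEA** \(=\sqrt{G\max(0,\chi^2-df)/(df\,N)}\) with G groups; 90% CI
  by inverting the noncentral chi-square. Reproduces 0.039 / 0.064 /
  0.071 / 0.093 from the corresponding chi-square/df/N.

## Multigroup procedure (two groups)

1. **Measurement Model**: per-group one-factor models, factor N(0,1) in
   both groups, no cross-group constraints (df 28 for 7 items).
2. **No Item Bias Model**: \(\lambda,\nu\) equal across groups; focal
   factor mean \(\kappa\) and variance \(\phi\) free (df 40). A
   significant chi-square difference vs. Step 1 (\(\alpha=.001\))
   indicates item bias and gates the search. Unique variances stay free
   per group and are never treated as bias.
3. **Iterative search**: free one equality (focal intercept = uniform
   bias; focal loading = nonuniform bias) at a time; adopt the candidate
   with the largest chi-square improvement if its 1-df test has
   p < .001; stop otherwise. Deterministic tie-breaks (lower item index,
   intercept before loading); freed parameters stay free.
4. **Effect sizes and true difference**: uniform bias
   \(d=(\nu^{foc}-\nu^{ref})/sd_{pooled}\), nonuniform
   \(d=\Delta\lambda\,\Delta\kappa/sd_{pooled}\), with
   \(sd_{pooled}=\sqrt{(1+\sigma^2_{foc})/2}\) model-implied; important
   if \(|d|>0.2\) and p < .001. The latent difference
   \(d=\kappa/\sqrt{(1+\phi)/2}\) is reported adjusted (Final Model) and
   unadjusted (No Item Bias Model).

## Multidimensional procedure (one group, measured violators)

Violators enter the model as exogenous observed variables correlating
freely with the factors; uniform bias appears as a direct violator->item
effect. The No Item Bias Model (all direct effects zero) provides the
global test: its exact-fit chi-square at \(\alpha=.001\) gates the
per-item search (the RMSEA >= .08 close-fit flag is also reported). The
search frees one direct effect at a time, as in the multigroup
procedure. Effect size is the standardized direct effect r (violators
and underlying items standardized); important if \(|r|>0.1\) and
p < .001. Trait-violator associations are reported adjusted and
unadjusted. Nonuniform (trait-by-violator) bias is *not* detectable by
this procedure — use the multigroup procedure.

## Ordinal logistic regression baseline

Per item, a proportional-odds model on the rest score (sum of the other
items; total score optional) plus the violator. The violator's log-odds
ratio with Wald p-value screens for uniform bias; |logOR| > 0.64 with
p < .001 is "important". Binary violators keep 0/1 coding; continuous
violators are per-SD.

## Synthetic data generator

`GeneratorSpec`/`simulate` draw a joint multivariate-normal latent layer
(factors, violator latents; binary violators by thresholding), build
underlying responses \(y=\nu+\lambda\xi+\text{bias}+\varepsilon\), and
discretize at fixed thresholds. Uniform bias adds
\(\text{size}\times V\) (group indicator, or standardized violator);
nonuniform bias adds \(\text{size}\times V\times\xi\). The injected size
is therefore the underlying-SD shift, verifiable on the returned latent
matrix. The generator emulates a two-subscale symptom questionnaire
(4-category items, staggered loadings 0.60-0.80, skewed category
proportions 35/30/20/15, factor correlation 0.8); it does not emulate
missing data, acquiescence styles, non-normal traits, or longitudinal
structure.

## Problem sizes used in the acceptance suites

The calibration/power claims are population-level; the CI suites run at
fixed, pre-registered sizes (seeds derived from one base seed):

* Type I: 200 no-DIF two-group replicates (n=1000/group) for the
  multigroup search; 100 one-group replicates (N=2000, 14 items,
  2 violators) for the multidimensional search.
* Power/localization: 60 replicates (multigroup) and 40 replicates
  (multidimensional) with 0.5-SD uniform DIF on one item.
* Bias absorption: 3 replicates at N=2500, two factor-2 items carrying
  age-related DIF with the true age-factor2 association 0; asserted as
  all unadjusted associations significantly negative and >= 2 of 3
  adjusted 95% intervals covering 0.
* Recovery: replicate-averaged estimates (20 x n=5000 two-group,
  10 x n=5000 one-group) within 0.05 of the generating values; single
  draws of \(\phi\) have sampling SD ~ 0.055 at this n, so the averaged
  form tests consistency at the stated tolerance.

## Limitations

* Forward greedy searches assume a majority of unbiased items. When
  roughly half a subscale is biased in the same direction, the "free the
  biased items" and "free the complementary items plus shift the
  factor-level parameter" solutions fit near-equivalently, and the
  search can select the wrong one. Inspect the signs and pattern of
  freed parameters when many items are flagged.
* The asymptotic covariance and all tests assume underlying bivariate
  normality; the per-pair RMSEA diagnostic flags gross violations but is
  not a formal test.
* The multidimensional procedure detects uniform bias only.
* Chi-square calibration is asymptotic; below ~300 observations per
  group the WLS statistic becomes conservative/erratic.
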