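# Methods

This note documents the statistical models, the synthetic data generator,
the numerical choices and the limitations of `clusterlasso`. Everything
described here is implemented and exercised by the package; nothing below
is an empirical claim about real hospital data.

## Problem setting

Administrative hospital data are *clustered*: patients are nested within
hospitals, and outcomes such as length of stay or in-hospital mortality
vary systematically between hospitals even after adjusting for patient
mix. Automated variable selection with the LASSO is attractive for
building risk-adjustment models from such data, but the penalty interacts
with the clustering: a variable whose apparent effect is really a
between-hospital difference (for example, the share of planned admissions,
which is partly a hospital-level property) can be selected as if it were a
patient-level risk factor. The package implements and compares three ways
of handling the hospital structure during LASSO selection.

## Models

All three variants fit a generalized linear model with an elastic-net
penalty on the patient-level coefficients. With linear predictor
`eta_i = beta_0 + x_i' beta (+ hospital term)` and outcome family either
gaussian (log length of stay) or binomial (mortality, logit link), the
penalized objective is

```
-(1/n) loglik(beta_0, beta) + lam * ( alpha*||beta||_1 + (1-alpha)/2*||beta||_2^2 )
```

where the gaussian negative log-likelihood is taken as `(1/2n)*RSS`. The
intercept is never penalized. `alpha = 1` is the pure LASSO;
`alpha = 0.99999` ("near-LASSO") behaves identically to the LASSO in
selection and prediction (this equivalence is asserted by the test suite)
while making the objective strictly convex.

* **no_hosps** — the hospital structure is ignored entirely.
* **hosps_fixed** — one reference-coded dummy indicator per hospital
  (first sorted label is the reference) is appended to the design and
  penalized like any other predictor.
* **hosps_random** — each hospital gets a random intercept
  `b_h ~ N(0, tau^2)`; the patient-level coefficients carry an L1 penalty
  while `tau` (and the residual SD `phi` in the gaussian case) are
  estimated. Predicted intercepts are BLUPs: shrunken cluster means with
  shrinkage `n_h / (n_h + phi^2/tau^2)`.

### Estimation

Fixed-effects variants use cyclic coordinate descent with
soft-thresholding on a weighted least-squares working problem. The
binomial family wraps the coordinate sweep in an IRLS outer loop (working
response `z = eta + (y - p)/w`, weights `w = p(1-p)` floored at `1e-5`).
Paths over a penalty grid are warm-started from the previous solution.
Fits are certified by their Karush-Kuhn-Tucker (KKT) subgradient
conditions: zero coefficients require `|x_j'r|/n <= lam*alpha`, active
ones require exact stationarity.

The mixed variant alternates, per outer iteration, (1) a joint
`(beta, b)` coordinate-descent solve at the current variance components —
the random intercepts enter as an unpenalized indicator block with ridge
`phi^2/(n tau^2)`, which is algebraically the BLUP shrinkage — and (2) an
EM-type fixed-point update of `tau^2` (and `phi^2`) iterated to
convergence at fixed residual statistics. For the binomial family the
working response is the penalized quasi-likelihood (PQL) linearization.
The reported log-likelihood is the exact gaussian marginal likelihood, or
a Laplace approximation at the predicted intercepts for binomial.
`tau -> 0` is an absorbing boundary solution (the model degenerates to
`no_hosps`) and is reported, not raised. Unpenalized mixed fits reproduce
the balanced one-way ML closed forms and match `statsmodels.MixedLM`
(ML) on unbalanced designs; both checks are in the test suite.

An optional **post** (relaxed-LASSO) estimator refits the selected support
without a penalty before evaluation.

## Penalty grid

The grid has exactly 100 log-linearly descending values. The top is the
KKT bound at the variant's null model (for `hosps_random`: the null mixed
model's residuals) inflated by a 5% safety factor; the bottom is
`lam_max * ratio` with `ratio` starting at `1e-3` and halved (up to 30
times) until the fit at grid position 5 selects at least one variable.
Both endpoint properties are certified by actually fitting the model.

## Tuning

Four criteria choose a point on the grid:

* `cv_min` — K-fold cross-validated deviance minimizer (deviance is MSE
  for gaussian, `-2 x` mean Bernoulli log-likelihood for binomial).
* `cv_1se` — the largest penalty within one standard error of that
  minimum (ties to the larger penalty). Not offered for `hosps_random`
  unless explicitly enabled.
* `aic` / `bic` — `-2 loglik + 2 df` and `-2 loglik + log(n) df`, with
  `df` = number of active coefficients + intercept (+ `tau`, + `phi`
  where estimated).

Fixed-effects variants use 10 row-wise folds; the mixed variant uses 5
cluster-aware folds built by dealing each hospital's shuffled rows
round-robin across folds, so that every training portion contains every
hospital (hospitals with fewer than 2 rows make such folding impossible
and raise an error).

## Evaluation protocol

Performance is estimated by repeated subsampling: R = 20 splits with
`|test| = round(n/20)`, constrained so every hospital keeps at least one
training row (an offending test row is moved back and a replacement is
drawn from hospitals that keep two or more training rows). Per split,
fold-level preprocessing (zero-variance removal, unit-variance scaling by
the training SD) is recomputed on the training portion only.

Metrics: RMSE on the log-outcome scale (gaussian); ROC AUC via the
Mann-Whitney rank statistic (ties count 1/2), area under the
precision-recall curve by step-wise interpolation over distinct
thresholds, Brier score, and the mean predictive Bernoulli likelihood
with probabilities clipped at `1e-12` (binomial).

Variable importance is a stability statistic: the share of replicates in
which a variable's absolute standardized coefficient ranks in the top 5
(ties broken by column order; replicates with fewer than 5 active
variables contribute what they have and are counted as shortfalls),
reported together with the mean coefficient over the replicates where the
variable made the top 5. Importance is computed from the CV-selected
(`cv_min`) fits.

## Preprocessing

In order: (gaussian only) rows with nonpositive outcome are removed and
the outcome is log-transformed; zero-variance predictors are dropped;
pairs with `|Pearson r| > 0.95` are broken by removing the member less
correlated with the outcome (visited in descending `|r|`, re-examined
after each removal); predictors are scaled to unit variance using
training-fold SDs (no centering — the intercept absorbs means).

## Synthetic generator

Real hospital administrative data of this kind are access-restricted, so
the package ships a generator that reproduces the *structure* of the
problem: H hospitals with sizes drawn uniformly from a range, ~30 binary
comorbidity indicators with prevalences drawn from a range, a
planned-admission indicator whose hospital-level mix is structural (a
fraction of hospitals has 0% planned admissions, a fraction has 100%, the
rest draw a prevalence from U(0.1, 0.9)), a hospital random intercept
with SD `tau` on the link scale, and either a positive continuous outcome
(`y = exp(eta + noise)`, modelled on the log scale) or a Bernoulli
outcome on the logit scale. Per-hospital RNG streams are spawned from a
single `SeedSequence`, so generation is bit-reproducible and insensitive
to hospital count changes in unrelated code paths.

The **confounded** variant moves the planned-admission effect entirely to
the hospital level: its within-hospital coefficient is forced to zero and
each hospital's intercept is shifted by `between_effect` times its
planned-admission rate. Within a hospital the variable then carries no
information, but ignoring the clustering makes it look strongly
predictive — the ecological-fallacy trap the random-intercept variant is
designed to avoid.

Preset scenarios (`los`, `mortality`, `confounded`, `recovery`) fix
hospital counts, size ranges, effect sizes and noise levels; see
`clusterlasso/synthetic.py` for the exact values and `README.md` for a
worked example.

## Numerical choices

* Coordinate descent: convergence when the largest coefficient update in
  a sweep is below `1e-7`; active-set sweeps between full sweeps; at most
  `1e5` sweeps.
* IRLS: deviance tolerance `1e-8`, at most 200 iterations; weights
  floored at `1e-5`; unpenalized binomial fits with `|eta| >= 30` raise a
  separation error.
* Mixed outer loop: parameter-change tolerance `1e-6`, at most 500
  iterations; variance fixed point iterated to `1e-10`; `tau^2` floored
  at `1e-12` before being declared zero.
* Grid: 100 values, safety factor 1.05, initial ratio `1e-3`.
* All seeds are expanded through `numpy.random.SeedSequence`; derived
  seeds are reduced modulo `2^31`. Two runs with the same configuration
  produce bit-identical CSV artifacts.

## Limitations

* Random *intercepts* only; random slopes and crossed random effects are
  out of scope.
* The binomial mixed likelihood is a Laplace/PQL approximation; its
  information criteria are approximate (the gaussian marginal likelihood
  is exact).
* The collinearity filter is pairwise; it does not detect higher-order
  linear dependence.
* Predictions for hospitals unseen at fit time are not defined for the
  cluster-aware variants (the evaluation protocol guarantees coverage
  instead of marginalizing over the random effect).
* The generator produces independent binary comorbidities; real
  comorbidity co-occurrence structure is not modelled beyond the optional
  collinear duplicates that the preprocessing filter exists to remove.
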