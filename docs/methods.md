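# Methods

## Scope and data flow

`immucast` estimates, smooths and projects childhood immunization
coverage from child-level household-survey records, and summarises
socioeconomic inequality in it.  The pipeline is

1. **survey prep** — design-weighted coverage per
   (country, region, year, indicator[, subgroup]) cell;
2. **spatio-temporal model** — a hierarchical logit-linear trend model
   with spatial random effects, fitted per indicator;
3. **trajectory** — projection to a horizon year, target exceedance,
   AARC;
4. **inequality** — SII/RII across wealth quintiles or education
   groups, with time changes and quadrant classification;
5. **evaluation** — DIC/WAIC, temporal hold-out AD/ME, full-vs-component
   consistency.

A synthetic-survey generator stands in for restricted microdata and
defines the conditions under which every simulation-based test runs.

## Survey estimation

Coverage cells are weighted proportions `p_hat = sum(w y)/sum(w)` over
children inside the configured age window (primary window 12–23
months; 12–35, 24–35, 24–59 and 12–59 are presets for sensitivity
analyses).  Sampling variance uses the Kish effective sample size
`n_eff = (sum w)^2 / sum w^2` rather than full linearization or
replication: the downstream model consumes `(round(n_eff p_hat),
round(n_eff))` as binomial counts, for which the weight-induced design
effect is the first-order correction.  Cluster and stratum identifiers
are retained so a linearized estimator could be added; intra-cluster
correlation beyond what the weights carry is therefore *not* reflected
in `n_eff`, which makes the binomial likelihood mildly anticonservative
on strongly clustered designs (visible as interval coverage slightly
below nominal in the calibration checks; see Limitations).

Extreme cells (`p_hat` of 0 or 1) are continuity-corrected to
`1/(2 n_eff)` from the boundary before any logit transform.  Empty
cells are emitted with `n = 0` and missing `p_hat`, never dropped
silently; cells below a configurable minimum size (default 10) carry a
`sparse` flag.  Full immunization is the conjunction of BCG, Polio3,
DPT3 and MCV1; records with any missing indicator are excluded with a
logged count.  Wealth quintiles come from the first principal component
of the standardized household asset matrix, sign-anchored to correlate
positively with total asset count, cut into weighted quintiles with
tie-aware mid-ranks (households with identical asset patterns move
between quintiles as a block).  Education is dichotomized as
primary-or-lower vs secondary-or-higher.

## The spatio-temporal model family

For region *i* in country *c*, centered year *t* and subgroup *s*:

```
logit p_its = mu + a_c + b_i + gamma_s + (beta + e_c + g_i + delta_s + h_is) t
```

* `mu`, `beta` — global intercept and trend (priors N(0, 5^2), N(0, 1));
* `a_c`, `e_c` — country intercept/slope deviations (variants `*_2`
  only), iid normal with PC-prior scales;
* `b_i` — spatial region effect: Besag (pure ICAR), BYM
  (`sigma_u u* + sigma_v v`), or BYM2
  (`sigma (sqrt(phi) u* + sqrt(1-phi) v)`) where `u*` is the
  variance-scaled ICAR component;
* `g_i` — iid region slope deviations;
* `gamma_s`, `delta_s`, `h_is` — subgroup offset, subgroup x time and
  region x subgroup slopes when the fit is stratified.

Time is centered at the median observed year, decorrelating intercepts
and slopes.  The six variant names map `*_1` to region effects only and
`*_2` to the added country level; this mapping is this package's
interpretation of the family, stated here because only the variant
names are conventionally fixed.  Stratified fits share one spatial
field across subgroups; fitting separate fields per subgroup was
considered and not implemented — with a shared graph and modest
subgroup counts the shared field is the identifiable choice.

The ICAR precision `Q` has `Q_ii = degree(i)`, `Q_ij = -1` for
neighbours.  Marginal variances are computed per connected component
from the Moore–Penrose pseudo-inverse (the covariance under the
component's sum-to-zero constraint), and `Q* = gm x Q` where `gm` is
the geometric mean of those variances, giving the structured component
unit typical variance so that `sigma` and `phi` are interpretable.
Isolated regions are flagged and receive only the unstructured
component; graphs with no edges at all drop the structured term for
BYM/BYM2 (with a diagnostic warning) and are an error for Besag
variants.  Sum-to-zero is enforced softly (sd 0.01 on each component
sum), keeping the posterior smooth for the Newton solver.

### Priors

Every standard deviation gets the penalized-complexity (exponential)
prior with `P(sigma > U) = alpha`: intercept-type scales use
`U = 1, alpha = 0.01` (a logit-scale effect above 1 is a priori rare);
slope-type scales use `U = 0.1, alpha = 0.01` (0.1 logit/yr sustained
for a decade is a full logit).  The BYM2 mixing proportion uses the
distance-based PC prior derived from the Kullback–Leibler divergence
between the BYM2 covariance and the unstructured base model, computed
from the eigenvalues of the scaled constrained structured covariance
and calibrated with `P(phi < 0.5) = 2/3`.  All are exposed on
`ModelSpec`.

### Inference

The model is latent Gaussian: conditional on the (at most six)
hyperparameters, the posterior of the standardized latent field is
log-concave under the binomial likelihood.  The default backend is a
nested Laplace approximation:

1. the field is parameterised non-centered (unit-scale blocks, with
   the hyperparameter scales applied as design-column multipliers), so
   the prior precision of the field is fixed;
2. for given hyperparameters the field conditional is maximised by
   damped Newton iterations (Cholesky solves);
3. hyperparameters are optimised on the Laplace-approximated marginal
   posterior (bounded L-BFGS on log/logit scales);
4. posterior draws sample the hyperparameters from a Gaussian
   approximation at their mode and, for each draw, the field from its
   conditional Gaussian at the re-solved mode.

A joint mode over field and scales would be degenerate (the
hierarchical funnel: the joint density is unbounded as a scale goes to
zero), which is why the hyperparameters are marginalised; this is the
same reasoning that motivates the approximate-inference engines
standard for these models, and it keeps a fit of 20 regions x 4
surveys under a second.  Draws are independent by construction, so the
convergence diagnostic is trivially satisfied (`rhat = 1`) and the
effective draw count equals the draw budget (default 1000).  An
affine-invariant ensemble MCMC backend (`fit(method="mcmc")`) samples
the same non-centered joint posterior and is used in the test suite to
cross-check posterior means; its split-chain rhat and effective sample
size are computed and attached, with a warning above the 1.01
threshold.

The Gaussian likelihood on `logit(p_hat)` with the design-based
standard error is available behind `ModelSpec(likelihood="gaussian")`
as a cross-check; binomial is the default because it respects
boundedness in small cells.

## Trajectory and targets

Projection extends each draw's own logit-linear trend (recovered
exactly by per-draw least squares on the logit scale, since model
surfaces are logit-linear by construction) to the horizon year; the
inverse logit keeps projections inside (0, 1) and intervals widen with
distance.  Exceedance probabilities are posterior tail fractions with
their Monte-Carlo standard errors.  AARC uses exponent `1/N` with `N`
the number of years in the interval; a `1/(N-1)` reading exists in
parts of the literature and is available by passing `N - 1`.  Required
additional AARC is floored at zero once a target is met.  National
aggregates are per-draw weighted means of regional draws; weights
default to equal within country, with effective-sample-size shares
(`n_eff_region_weights`) or external population weights accepted.  A
region counts as "projected to reach" a target when its exceedance
probability is at least 0.5 (configurable).  The best-performing-region
scenario compounds the per-draw AARC of the region with the highest
posterior-mean AARC over the reference period onto the national
trajectory; its baseline compounds the national AARC by the same rule,
so the two coincide exactly when regions are identical.

## Inequality indices

Groups ordered disadvantaged to advantaged are placed at ridit
midpoints (cumulative share below + half own share).  Per posterior
draw, coverage is regressed on the midpoint by weighted least squares
with the shares as weights; SII is `100 x (fit(1) - fit(0))` in
percentage points and RII is `fit(1)/fit(0)` with fitted extremes
clipped to `(1e-6, 1]`.  Regression-based indices (not the simple
richest-minus-poorest gap, which is provided as `method="gap"` for
cross-checks) are the standard construction and use all five
quintiles.  SII can be negative, so its change over time is the
absolute annual change `(SII_n - SII_0)/N`; RII is positive and uses
AARC.  Joint changes are classified: group 1 both declining, group 2
SII declining but not RII, group 3 RII declining but not SII, group 4
both worsening — "declining" requires the 95% equal-tailed CrI upper
bound below zero, "worsening" the lower bound above zero, and when
neither index moves significantly the point-estimate signs decide with
a non-significant flag.  Wealth shares are 0.2 by construction;
education shares come from the weighted data.

## Evaluation

WAIC is `-2(lppd - p_waic)` with `lppd = sum_i log mean_d exp(ll_id)`
and `p_waic = sum_i var_d(ll_id)`; an optional draw-weight vector
supports deterministic (quadrature-node) posterior representations, in
which case the population-variance form is used.  DIC is
`D(mean) + 2 p_D` with `p_D = mean(D) - D(mean)`, deviance evaluated
at the posterior-mean linear predictor.  Hold-out validation fits on
years up to the split (e.g. train to 2016, hold out the final years),
projects across the held-out years, and reports mean absolute
difference and mean error in percentage points against the design-based
cell estimates — positive out-of-sample ME means overprediction.
Model selection ranks variants by rank-sum over DIC, WAIC, out-of-sample
AD and |out-of-sample ME|, ties broken toward the simpler variant; the
combination rule is this package's choice since only the criteria
themselves are conventionally fixed.  The consistency check flags
(region, year) cells whose posterior-mean full-immunization coverage
exceeds the smallest component vaccine's by more than 0.5 percentage
points (the indicators are fitted independently, so small excesses can
occur).

## Synthetic data: what it emulates, and what it does not

The generator draws a true surface from the same family the model
assumes: country intercepts/slopes around `logit(0.70)` and 0.05
logit/yr (sd 0.4 and 0.02), BYM2 region effects (`sigma = 0.35`,
`phi = 0.6`), region slope deviations (sd 0.02 logit/yr), a wealth
gradient of 0.8 logit across the ridit range narrowing by 0.015/yr, an
education gradient of 0.5 narrowing by 0.008/yr, and per-vaccine
offsets (BCG +0.8 ... MCV1 −0.3 logit).  These defaults sketch the
African DHS-era landscape of improving-but-unequal coverage and are
the fixed conditions of all calibration checks.  Surveys are stratified
two-stage cluster samples (2 strata x 10 clusters x 20 children per
region-year by default ≈ 400 children), with lognormal stratum base
weights, lognormal child-level weight dispersion truncated at its
1st/99th percentiles, cluster intercepts (sd 0.25), and a shared
per-child propensity (sd 0.8) that correlates the four vaccines so
full immunization is not the product of independent margins.  Household
assets load on the latent wealth score so the PCA wealth index recovers
the ranking; education is generated from the same latent score.  Child
ages are uniform on 0–59 months and indicators do not depend on age, so
age-window selection changes denominators, not truth — schedule-aware
age effects, card-vs-recall measurement error, geographic coordinates
and boundary changes are all *not* emulated.  A trend-break switch
(`with_trend_break`) flattens or damps all trends after a chosen year
to emulate recent-period stagnation for hold-out and
recent-window-sensitivity checks.

Recovery targets are population quantities: marginal coverage per
region-year integrates the child propensity and cluster effect by
Gauss–Hermite quadrature and averages the wealth x education mixture;
true region slopes are least-squares slopes of logit marginal coverage
over the truth years.  Passing tests therefore show that the pipeline
recovers the population surface of a correctly specified,
moderately-clustered survey world — not that it is robust to real-data
features the generator omits.

## Numerical choices

* Binomial counts are rounded Kish effective counts, floored at 1.
* Newton iterations: step-halving line search, convergence on relative
  objective change `1e-10`, working weights floored at `1e-10`;
  linear predictors clipped at ±35 before `expit`.
* Hyperparameter bounds: log-scales in [−8, 3], logit-phi in [−6, 6];
  draws are clipped to the same box.
* The hyperparameter Hessian is central-difference (step `1e-3`) with
  eigenvalues floored at `1e-6` before inversion.
* The phi PC prior solves its rate by bracketed root finding; if the
  requested quantile is unattainable (`d(U)/d(1) >= alpha`) the prior
  degrades to uniform-in-distance.
* Ridit ties: identical PCA scores (rounded at 1e-9) share a weighted
  mid-rank.
* Empty-cell emission enumerates the observed key product per surveyed
  country-year, so a region surveyed in one year but not another shows
  up explicitly.

## Problem sizes

Simulation-based checks run at 2 countries x 10 regions, four surveys
(2003/2008/2013/2018), ~400 children per region-year, 50 replicates
for recovery and hold-out properties, and 1000 posterior draws per
fit; the end-to-end acceptance run uses 2 countries x 6 regions with
four surveys from 2000 to 2019.  These sizes were chosen as the
smallest at which the spatial, temporal and survey-design structure
all remain active.

## Known limitations

* Kish-only design adjustment understates clustering; empirical 95%
  CrI coverage sits near 0.90–0.93 rather than 0.95 under the
  generator's cluster effect.
* The Laplace hyperparameter Gaussian ignores skew in the posteriors
  of `sigma` and `phi`; grid or CCD integration would refine it.
* Projections assume the logit-linear trend continues; the trend-break
  generator exists precisely to quantify the resulting overprediction
  under stagnation, and recent-window fits are the mitigation offered.
* National aggregation weights are proxies (equal or `n_eff` shares)
  unless population weights are supplied.
* Isolated regions lose the structured variance share
  (`b_i = sigma sqrt(1-phi) v_i`), slightly shrinking their effect
  scale relative to connected regions.
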