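# Methods

## The estimation problem

Spontaneous-report pharmacovigilance databases record a suspected adverse
drug reaction only when it has already occurred at the date of analysis.
For a reported case `i`, write `x_i` for the time-to-onset (lag from
treatment initiation to the reaction) and `t_i` for the truncation time
(lag from treatment initiation to the analysis date).  Inclusion in the
database requires `x_i <= t_i`: the data are *right-truncated*, with a
different truncation time per case.  Patients whose reaction lies in the
future are entirely absent — this is selection, not censoring, and
ignoring it biases any estimate of the time-to-onset distribution `F`.

Two likelihoods are implemented for a parametric family `f(x; theta)`:

* **naive** — `L1(theta) = prod_i f(x_i; theta)`, which pretends the
  sample is unselected;
* **truncation-based (TBE)** — `L2(theta) = prod_i f(x_i; theta) /
  F(t_i; theta)`, the product of the conditional densities of `X_i`
  given `X_i <= t_i`, which is the correct likelihood under right
  truncation.

The non-parametric counterpart is the product-limit estimator of the
*conditional* distribution `F(x)/F(t*)`, with `t*` the largest observed
truncation time:

```
F(x)/F(t*) = prod_{v_j > x} (1 - n_j / N_j),
n_j = #{i : x_i = v_j},    N_j = #{i : x_i <= v_j <= t_i},
```

over the distinct onset times `v_j`.  The unconditional `F` is not
non-parametrically identifiable because `F(t*)` is unknown; this is
precisely why the parametric TBE is of practical interest — it recovers
the unconditional distribution, and with it the observable probability
`p = F(t*; theta)` and the expected time-to-onset.

## Distribution families

Three families cover the hazard shapes commonly seen for adverse-drug
reactions, each with a rate-like scale `lam` (units 1/time) multiplying
time directly and, for the two-parameter families, a dimensionless shape
`beta`:

| family       | density                                            | mean                              |
|--------------|----------------------------------------------------|-----------------------------------|
| exponential  | `lam e^{-lam x}`                                   | `1/lam`                           |
| Weibull      | `lam beta (lam x)^{beta-1} e^{-(lam x)^beta}`      | `Gamma(1 + 1/beta)/lam`           |
| log-logistic | `lam beta (lam x)^{beta-1} / (1 + (lam x)^beta)^2` | `(pi/beta)/(lam sin(pi/beta))`, only for `beta > 1` |

The log-logistic mean does not exist for `beta <= 1`; the package raises
an explicit `UndefinedMeanError` rather than returning NaN, and the
bootstrap excludes (and counts) resamples whose refitted shape falls in
that region.  Log-density and log-CDF are evaluated in closed form (not
as `log(pdf)`) so likelihoods stay finite for extreme draws; `x = 0` is
outside the support and a domain error.  Conversions to the scipy
parameterization (`scale = 1/lam`) are confined to `as_scipy`, which the
tests use as an independent cross-check.

## Fitting, and what counts as a failed maximization

The naive exponential fit is closed-form (`lam = n / sum x`).  All other
fits maximize the chosen log-likelihood by BFGS over `(log lam, log
beta)`, making positivity structural.  Starts: `lam` from the closed-form
exponential rate, `beta = 1`; TBE fits are warm-started from the
converged naive fit of the same family.  On failure one retry runs from
a multiplicatively jittered start (x0.5 / x2 per coordinate).

A fit is **converged** when the objective is finite at the solution, the
iteration cap (500) was not hit, the optimizer reports success *or* the
final gradient inf-norm (mean-loglik scale) is below `1e-5`, and the
solution is away from the transformation boundary.  The boundary clause
matters: under heavy truncation the conditional likelihood can increase
monotonically into the `lam -> 0` limit, where `F(x)/F(t)` degenerates
to a truncation-window distribution that no longer identifies `lam`.
Empirically these runaway solutions sit many orders of magnitude below
the interior mode with a wide empty gap between the two clusters, so
"more than a factor `1e4` (log scale) from the start" flags them
robustly.  Non-converged fits are *problem-of-maximization* (NPM)
events: reported, excluded from Monte-Carlo summaries (per method — a
replication dropped for the TBE still counts for the naive summary), and
never raised as exceptions.  Because the failure criterion of any
particular optimizer is implementation-specific, NPM counts are
descriptive output, not asserted constants.

## Monte-Carlo study design

A scenario is `(family, theta, p, n)`.  The truncation bound `tau` is
derived as the `p`-quantile of the true distribution, so `p = P(X <
tau)` is the probability of an onset falling inside the observable
window.  Pairs `(X, T)` are drawn independently — `X` by inverse-CDF
sampling, `T` uniform on `[0, tau]` — and a pair is accepted when
`X <= T`; rejected pairs are fully redrawn (both coordinates) until `n`
pairs are accepted, with a guard at 10^7 total draws.  The default grid
is the full factorial design: `lam` in {0.05, 1}, `beta` in {0.5, 2},
`p` in {0.25, 0.5, 0.8}, `n` in {100, 500} — 12 exponential + 24
Weibull + 24 log-logistic = 60 scenarios, 1000 replications each by
default.

Seeding is hierarchical (`numpy.random.SeedSequence`: master seed →
per-scenario stream → per-replication stream) so every scenario and
replication is independently reproducible; identical seeds give
bit-identical samples and summaries.

Per scenario and method, the engine reports per-coordinate bias
`mean(theta_hat - theta)`, MSE `mean((theta_hat - theta)^2)`, the
proportion of replications with `theta_hat > theta`, the NPM count and
the effective replication count.

## Derived summaries and the bootstrap

From a converged TBE fit: `p_hat = F(t*; theta_hat)` and the expected
time-to-onset from the family mean.  Confidence intervals use the BCa
bootstrap: cases are resampled with replacement as `(x, t)` *pairs*
(preserving `x <= t` by construction), the model is refitted per
resample, the bias-correction `z0` comes from the fraction of bootstrap
statistics below the point estimate, and the acceleration `a` from
jackknife influence values.  Non-converged resamples are dropped and
counted; if fewer than half the resamples yield a usable statistic the
interval is flagged unreliable.  When a leave-one-out statistic is
undefined, `a` falls back to 0 (bias-corrected percentile) with a note.
Percentile bounds on the same draws are always reported alongside.

## Goodness of fit

`gof_curves` implements the graphical check of Lawless for
right-truncated data: conditional fitted survivals
`1 - F(x; theta_hat)/F(t*; theta_hat)` overlaid on the non-parametric
conditional survival, plus the unconditional fitted survivals, on a
common grid (default 200 points over `[min x, t*]`, with the exact step
locations added).  The sup-distance between each conditional parametric
curve and the NPMLE is reported as a descriptive closeness measure —
there is no formal test; hypothesis testing for right-truncated
goodness of fit is out of scope.

## What the synthetic generator does and does not emulate

The generator reproduces the selection mechanism (independent onset and
truncation times, uniform truncation, rejection until `n` accepted)
exactly.  It does not emulate features of real spontaneous-report data:
under-reporting (assumed uniform in the modelling, and absent here),
reporting delays, duplicate or erroneous reports, rounding of dates to
weeks, or dependence between exposure uptake and calendar time.  Passing
tests therefore demonstrate correctness of the estimators under the
stated sampling model, not robustness to those artefacts.

## Numerical choices and problem sizes

* Optimizer: BFGS, `gtol 1e-8`, 500 iterations max; one jittered retry.
* Quantile/CDF round-trips hold to 1e-10 relative; likelihood identities
  (TBE >= naive; equality in the untruncated limit) to 1e-6 relative.
* Ties `x_i = t_i` are valid observations (the observability condition
  is inclusive).
* The NPMLE uses the right-continuity convention: the value at `v_j`
  includes the jump at `v_j` (the product runs over `v_j > x` strictly).
  Risk counts use the literal indicator definition, including ties
  between onset and truncation values.
* Replication counts: the validation suite runs pinned scenarios at 1000
  replications where the fits are cheap (exponential) and at 250
  elsewhere, with all Monte-Carlo comparisons expressed in standard
  errors estimated from the replication spread; the acceptance script
  runs every pinned scenario at 1000.  The bootstrap coverage study runs
  at reduced scale (50 outer replications, 200 resamples, n = 40).
* The lymphoma-like demonstration fixture is synthetic: 64 cases drawn
  from a Weibull with `lam = 0.00468`, `beta = 1.49` and `t*` near 529
  weeks, mimicking the shape of the published application; the real
  French pharmacovigilance dataset is not public and is not distributed.

## Known limitations

* Only the exponential, Weibull and log-logistic families are provided;
  gamma, log-normal and mixtures are out of scope, as are regression
  models on risk factors and joint random-truncation modelling of
  `(X, T)`.
* Standard errors from the observed information matrix are not
  implemented; uncertainty comes from the bootstrap.
* NPM counts are optimizer-definition dependent (see above); comparing
  them across implementations is qualitative only.
* The boundary-collapse phenomenon means some model/data combinations
  (e.g. an exponential fitted to strongly late-onset truncated data)
  genuinely have no interior TBE maximum; the package reports this as a
  failed maximization rather than inventing an estimate.
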