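# rtrunc — time-to-onset estimation from right-truncated spontaneous reports

Spontaneous-report pharmacovigilance databases only contain the adverse
drug reactions that have *already happened* at the date of analysis.
For each reported case, the time-to-onset `x` (treatment start →
reaction) is observed together with a truncation time `t` (treatment
start → analysis date), and inclusion requires `x ≤ t`.  Estimating the
time-to-onset distribution from such data with ordinary likelihood
methods is biased — sometimes severely — because the cases still to come
are missing entirely (right truncation, not censoring).

`rtrunc` is for pharmacoepidemiologists and biostatisticians who want to
estimate time-to-onset distributions from reporting databases properly.
It provides:

* **Parametric ML fitting** of exponential, Weibull and log-logistic
  models under two likelihoods: the *naive* one, `L1 = ∏ f(x_i; θ)`,
  and the truncation-corrected one,
  `L2 = ∏ f(x_i; θ)/F(t_i; θ)` (the **truncation-based estimator**,
  TBE), with explicit detection of failed maximizations;
* the **conditional non-parametric MLE** (product-limit estimator)
  `F(x)/F(t*) = ∏_{v_j > x} (1 − n_j/N_j)`, the reference curve for a
  graphical goodness-of-fit check;
* **derived summaries**: the observable probability
  `p̂ = F(t*; θ̂_TBE)`, the expected time-to-onset, and BCa bootstrap
  confidence intervals (pair resampling, jackknife acceleration);
* a **Monte-Carlo engine** that draws right-truncated samples (onset
  from the chosen family, truncation uniform on `[0, τ]` with
  `P(X < τ) = p`, rejection until `n` accepted) and measures bias, MSE
  and over-estimation proportions of both estimators over a scenario
  grid.

See `docs/methods.md` for the model, the failed-maximization definition
and the numerical choices.

## Worked example

Create a synthetic 64-case dataset shaped like a lymphoma-after-biologic
signal (Weibull onsets, `λ = 0.00468`, `β = 1.49`, observation window
about 10 years) and fit a Weibull with both likelihoods:

```bash
rtrunc fixture --family weibull --theta 0.00468 1.49 --p 0.979 --n 64 \
       --seed 529 --out lymphoma_like.csv
rtrunc fit lymphoma_like.csv --family weibull --method naive tbe
```

Output (abridged):

```json
{
  "n": 64,
  "t_star": 524.4494946,
  "fits": [
    {"method": "naive", "theta": [0.00539, 2.024],
     "p_hat": 0.9997, "expected_time_to_onset": 164.5},
    {"method": "tbe",   "theta": [0.00472, 2.012],
     "p_hat": 0.9980, "expected_time_to_onset": 187.6}
  ]
}
```

The naive fit inflates the rate parameter and shortens the expected
time-to-onset (164.5 weeks) relative to the truncation-based fit
(187.6 weeks) — the naive estimator systematically overestimates λ
because late-onset cases are missing from the data.  Even here, with
`p̂ ≈ 1` (nearly the whole distribution inside the observation window),
the gap is over 20 weeks; it widens dramatically as `p` falls.

Other subcommands: `rtrunc npmle` (conditional product-limit step
function as CSV), `rtrunc gof` (conditional/unconditional survival
overlays plus sup-distances to the NPMLE), `rtrunc simulate` (scenario
grid → summary CSV; the default configuration is the full 60-scenario
factorial design at 1000 replications).

The same functionality is available as a library:

```python
import rtrunc as rt

sample = rt.read_cases("lymphoma_like.csv", unit="weeks")
tbe = rt.fit(sample, "weibull", method="tbe")
print(rt.estimate_p(tbe, sample.t_star), rt.expected_tto(tbe))
ci = rt.bootstrap_ci(sample, "weibull", statistic="mean", n_boot=5000, seed=1)
print(ci.lower, ci.upper)
```

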