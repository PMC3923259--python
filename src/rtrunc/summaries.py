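"""Derived quantities for a fitted time-to-onset model.

From a truncation-based fit one can recover the *unconditional*
distribution, and with it two quantities of direct pharmacovigilance
interest: the probability ``p = F(t*; theta)`` that a time-to-onset
falls inside the observable window (its complement lower-bounds the
fraction of cases still to come), and the expected time-to-onset.
Uncertainty is quantified by a bias-corrected and accelerated (BCa)
bootstrap over case resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from . import distributions as dist
from .distributions import FamilySpec, UndefinedMeanError
from .estimation import FitResult, TruncatedSample, fit

__all__ = [
    "BootstrapInterval",
    "estimate_p",
    "expected_tto",
    "bootstrap_ci",
    "application_report",
]

STATISTICS = ("mean", "lambda", "beta", "p_hat")


def estimate_p(fit_result: FitResult, t_star: float) -> float:
    """Estimated probability of onset within the observable window.

    Evaluates the fitted CDF at the maximum observed truncation time,
    ``F(t*; theta_hat)``.  Monotone non-decreasing in ``t_star`` and
    tends to 1 as ``t_star`` grows.
    """
    if not fit_result.converged:
        raise ValueError("cannot derive p-hat from a non-converged fit")
    return float(dist.cdf(fit_result.spec, t_star))


def expected_tto(fit_result: FitResult) -> float:
    """Expected time-to-onset implied by the fitted model.

    Raises
    ------
    UndefinedMeanError
        Propagated when the fitted family has no finite mean
        (log-logistic with shape at or below 1).
    """
    if not fit_result.converged:
        raise ValueError("cannot derive an expectation from a non-converged fit")
    return float(dist.mean(fit_result.spec))


@dataclass
class BootstrapInterval:
    """A BCa bootstrap confidence interval for one statistic.

    ``n_failed`` counts resamples whose refit did not converge and
    ``n_undefined`` counts resamples where the statistic does not exist
    (e.g. the log-logistic mean with fitted shape <= 1); both kinds are
    excluded from the order statistics.  ``unreliable`` is set when
    fewer than half the resamples produced a usable statistic.
    Percentile bounds on the same draws are reported alongside.
    """

    statistic: str
    point: float
    lower: float
    upper: float
    level: float
    n_boot: int
    method: str = "BCa"
    seed: int | None = None
    percentile_lower: float = np.nan
    percentile_upper: float = np.nan
    n_failed: int = 0
    n_undefined: int = 0
    acceleration: float = 0.0
    bias_correction: float = 0.0
    unreliable: bool = False
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "point": self.point,
            "lower": self.lower,
            "upper": self.upper,
            "level": self.level,
            "n_boot": self.n_boot,
            "method": self.method,
            "seed": self.seed,
            "percentile_lower": self.percentile_lower,
            "percentile_upper": self.percentile_upper,
            "n_failed": self.n_failed,
            "n_undefined": self.n_undefined,
            "unreliable": self.unreliable,
        }


def _statistic_value(
    statistic: str, fit_result: FitResult, t_star: float
) -> float | None:
    """Value of the named statistic, or None when it is undefined."""
    spec = fit_result.spec
    if statistic == "lambda":
        return spec.lam
    if statistic == "beta":
        if len(spec.theta) < 2:
            raise ValueError("the exponential family has no shape parameter")
        return spec.beta
    if statistic == "p_hat":
        return float(dist.cdf(spec, t_star))
    if statistic == "mean":
        try:
            return float(dist.mean(spec))
        except UndefinedMeanError:
            return None
    raise ValueError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")


def _bca_bounds(theta_boot: np.ndarray, point: float, z0: float, a: float,
                level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    bounds = []
    for q in (alpha / 2.0, 1.0 - alpha / 2.0):
        z = ndtri(q)
        adj = ndtr(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
        bounds.append(float(np.quantile(theta_boot, adj)))
    return bounds[0], bounds[1]


def bootstrap_ci(
    sample: TruncatedSample,
    family: str,
    method: str = "tbe",
    statistic: str = "mean",
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapInterval:
    """BCa bootstrap interval for a derived statistic of one fit.

    Cases are resampled with replacement as ``(x, t)`` pairs, which
    preserves the observability constraint by construction; the model is
    refitted on every resample (warm-started from the full-sample fit).
    The bias-correction constant ``z0`` comes from the fraction of
    bootstrap statistics below the point estimate and the acceleration
    ``a`` from jackknife (leave-one-out) influence values; when a
    jackknife statistic is undefined, ``a`` falls back to 0 (the
    bias-corrected percentile interval) with a note.

    ``p_hat`` is always evaluated at the *original* sample's ``t*`` so
    that the statistic has the same meaning on every resample.
    """
    if sample.n < 2:
        raise ValueError("bootstrap needs at least two cases")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")

    rng = np.random.default_rng(seed)
    t_star = sample.t_star
    full_fit = fit(sample, family, method=method)
    if not full_fit.converged:
        raise ValueError("full-sample fit did not converge; no interval")
    point = _statistic_value(statistic, full_fit, t_star)
    if point is None:
        raise UndefinedMeanError(
            "the statistic is undefined at the full-sample fit"
        )

    notes: list[str] = []
    n = sample.n
    values = np.full(n_boot, np.nan)
    n_failed = 0
    n_undefined = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = TruncatedSample(sample.x[idx], sample.t[idx], unit=sample.unit)
        res = fit(boot, family, method=method, init=full_fit.spec)
        if not res.converged:
            n_failed += 1
            continue
        v = _statistic_value(statistic, res, t_star)
        if v is None:
            n_undefined += 1
            continue
        values[b] = v
    theta_boot = values[np.isfinite(values)]
    unreliable = theta_boot.size < n_boot / 2
    if theta_boot.size < 2:
        raise RuntimeError("too few usable bootstrap resamples to form an interval")

    # bias correction: clamp the proportion away from 0/1 so z0 is finite
    prop = np.clip(
        np.mean(theta_boot < point), 1.0 / (theta_boot.size + 1),
        theta_boot.size / (theta_boot.size + 1.0),
    )
    z0 = float(ndtri(prop))

    # jackknife acceleration
    a = 0.0
    jack = np.full(n, np.nan)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        loo = TruncatedSample(sample.x[mask], sample.t[mask], unit=sample.unit)
        mask[i] = True
        res = fit(loo, family, method=method, init=full_fit.spec)
        v = _statistic_value(statistic, res, t_star) if res.converged else None
        if v is None:
            jack = None
            break
        jack[i] = v
    if jack is None:
        notes.append("jackknife statistic undefined for some leave-one-out set; a=0")
    else:
        d = jack.mean() - jack
        denom = 6.0 * np.sum(d ** 2) ** 1.5
        a = float(np.sum(d ** 3) / denom) if denom > 0 else 0.0

    lower, upper = _bca_bounds(theta_boot, point, z0, a, level)
    alpha = 1.0 - level
    p_lo = float(np.quantile(theta_boot, alpha / 2.0))
    p_hi = float(np.quantile(theta_boot, 1.0 - alpha / 2.0))

    return BootstrapInterval(
        statistic=statistic,
        point=float(point),
        lower=lower,
        upper=upper,
        level=level,
        n_boot=n_boot,
        seed=seed,
        percentile_lower=p_lo,
        percentile_upper=p_hi,
        n_failed=n_failed,
        n_undefined=n_undefined,
        acceleration=a,
        bias_correction=z0,
        unreliable=unreliable,
        notes=notes,
    )


def application_report(
    sample: TruncatedSample,
    families: Sequence[str] = ("exponential", "weibull", "loglogistic"),
    n_boot: int = 0,
    level: float = 0.95,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-family report: naive and TBE estimates, p-hat and expectations.

    One row per family with the naive and truncation-based parameter
    estimates, the observable probability ``p_hat = F(t*; theta_TBE)``
    and the expected times-to-onset under both fits; with ``n_boot > 0``
    a BCa interval for the TBE expectation is appended.  Expectations
    that do not exist are reported as NaN with a flag column.
    """
    rows = []
    t_star = sample.t_star
    for fam in families:
        naive = fit(sample, fam, method="naive")
        tbe = fit(sample, fam, method="tbe")
        row: dict = {"family": fam, "t_star": t_star}
        for tag, f in (("naive", naive), ("tbe", tbe)):
            row[f"{tag}_converged"] = f.converged
            row[f"{tag}_lambda"] = f.spec.lam if f.converged else np.nan
            row[f"{tag}_beta"] = (
                f.spec.beta if f.converged and len(f.spec.theta) > 1 else np.nan
            )
            if f.converged:
                try:
                    row[f"{tag}_expectation"] = expected_tto(f)
                    row[f"{tag}_mean_defined"] = True
                except UndefinedMeanError:
                    row[f"{tag}_expectation"] = np.nan
                    row[f"{tag}_mean_defined"] = False
            else:
                row[f"{tag}_expectation"] = np.nan
                row[f"{tag}_mean_defined"] = False
        row["p_hat"] = estimate_p(tbe, t_star) if tbe.converged else np.nan
        if n_boot and tbe.converged and row["tbe_mean_defined"]:
            ci = bootstrap_ci(
                sample, fam, method="tbe", statistic="mean",
                n_boot=n_boot, level=level, seed=seed,
            )
            row["tbe_expectation_lower"] = ci.lower
            row["tbe_expectation_upper"] = ci.upper
        rows.append(row)
    return pd.DataFrame(rows)
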