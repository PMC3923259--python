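"""Time-to-onset distribution families.

Three parametric families cover the range of hazard shapes seen in
pharmacovigilance time-to-onset data: the exponential (constant hazard),
the Weibull (monotone hazard, increasing for ``beta > 1``) and the
log-logistic (unimodal hazard for ``beta > 1``).  All three are
parameterized with a rate-like scale parameter ``lam`` that multiplies
time directly, i.e. the Weibull density is
``lam * beta * (lam*x)**(beta-1) * exp(-(lam*x)**beta)``.  This differs
from the scipy convention (``scale = 1/lam``); :func:`as_scipy` performs
the conversion.

Log-densities and log-CDFs are evaluated in closed form rather than as
``log(pdf)`` so that likelihood evaluations stay finite for extreme draws.
The support is strictly positive time; ``x = 0`` is a domain error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "FAMILIES",
    "N_PARAMS",
    "FamilySpec",
    "UndefinedMeanError",
    "density",
    "log_density",
    "cdf",
    "log_cdf",
    "survival",
    "quantile",
    "mean",
    "rvs",
    "as_scipy",
]

FAMILIES = ("exponential", "weibull", "loglogistic")
N_PARAMS = {"exponential": 1, "weibull": 2, "loglogistic": 2}


class UndefinedMeanError(ValueError):
    """Raised when the requested family/parameter combination has no finite mean.

    The log-logistic distribution has no first moment when the shape
    parameter ``beta`` is at or below 1 (heavy right tail).
    """


@dataclass(frozen=True)
class FamilySpec:
    """A distribution family together with its parameter vector.

    Parameters
    ----------
    family : str
        One of ``"exponential"``, ``"weibull"``, ``"loglogistic"``.
    theta : tuple of float
        ``(lam,)`` for the exponential family, ``(lam, beta)`` otherwise.
        ``lam`` has units 1/time and ``beta`` is dimensionless; both must
        be strictly positive.
    """

    family: str
    theta: tuple

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        theta = tuple(float(v) for v in self.theta)
        object.__setattr__(self, "theta", theta)
        k = N_PARAMS[self.family]
        if len(theta) != k:
            raise ValueError(
                f"{self.family} takes {k} parameter(s), got {len(theta)}"
            )
        if not all(math.isfinite(v) and v > 0 for v in theta):
            raise ValueError(f"parameters must be positive and finite, got {theta}")

    @property
    def lam(self) -> float:
        """Rate-like scale parameter (1/time)."""
        return self.theta[0]

    @property
    def beta(self) -> float:
        """Shape parameter; 1.0 for the exponential family."""
        return self.theta[1] if len(self.theta) > 1 else 1.0


def _check_x(x):
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("times must be strictly positive and finite")
    return x


def log_density(spec: FamilySpec, x) -> np.ndarray:
    """Log of the density ``f(x; theta)``, evaluated in closed form."""
    x = _check_x(x)
    lam, beta = spec.lam, spec.beta
    lx = lam * x
    if spec.family == "exponential":
        return np.log(lam) - lx
    log_lx = np.log(lx)
    base = np.log(lam) + np.log(beta) + (beta - 1.0) * log_lx
    if spec.family == "weibull":
        with np.errstate(over="ignore"):
            return base - np.exp(beta * log_lx)
    # log-logistic: density lam*beta*(lam x)^(beta-1) / (1 + (lam x)^beta)^2
    return base - 2.0 * np.logaddexp(0.0, beta * log_lx)


def density(spec: FamilySpec, x) -> np.ndarray:
    """Density ``f(x; theta)`` of the time-to-onset distribution."""
    return np.exp(log_density(spec, x))


def log_cdf(spec: FamilySpec, x) -> np.ndarray:
    """Log of the distribution function ``F(x; theta)``."""
    x = _check_x(x)
    lam, beta = spec.lam, spec.beta
    if spec.family == "exponential":
        u = lam * x
    elif spec.family == "weibull":
        with np.errstate(over="ignore"):
            u = np.exp(beta * np.log(lam * x))
    else:
        # F(x) = 1 / (1 + (lam x)^-beta)
        return -np.logaddexp(0.0, -beta * np.log(lam * x))
    with np.errstate(divide="ignore"):
        return np.log(-np.expm1(-u))


def cdf(spec: FamilySpec, x) -> np.ndarray:
    """Distribution function ``F(x; theta)``; monotone, tends to 1."""
    return np.exp(log_cdf(spec, x))


def survival(spec: FamilySpec, x) -> np.ndarray:
    """Survival function ``1 - F(x; theta)`` in closed form."""
    x = _check_x(x)
    lam, beta = spec.lam, spec.beta
    if spec.family == "exponential":
        return np.exp(-lam * x)
    if spec.family == "weibull":
        with np.errstate(over="ignore"):
            return np.exp(-np.exp(beta * np.log(lam * x)))
    return np.exp(-np.logaddexp(0.0, beta * np.log(lam * x)))


def quantile(spec: FamilySpec, q) -> np.ndarray:
    """Closed-form inverse of :func:`cdf`.

    ``cdf(spec, quantile(spec, q)) == q`` to numerical tolerance for
    ``q`` in the open unit interval.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("quantile level must lie strictly between 0 and 1")
    lam, beta = spec.lam, spec.beta
    if spec.family == "exponential":
        return -np.log1p(-q) / lam
    if spec.family == "weibull":
        return np.power(-np.log1p(-q), 1.0 / beta) / lam
    return np.power(q / (1.0 - q), 1.0 / beta) / lam


def mean(spec: FamilySpec) -> float:
    """Expected time-to-onset.

    Raises
    ------
    UndefinedMeanError
        For the log-logistic family with ``beta <= 1``, whose mean does
        not exist.
    """
    lam, beta = spec.lam, spec.beta
    if spec.family == "exponential":
        return 1.0 / lam
    if spec.family == "weibull":
        return special.gamma(1.0 + 1.0 / beta) / lam
    if beta <= 1.0:
        raise UndefinedMeanError(
            f"log-logistic mean does not exist for beta={beta} <= 1"
        )
    return (math.pi / beta) / (lam * math.sin(math.pi / beta))


def rvs(spec: FamilySpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` variates by inverse-CDF sampling."""
    u = rng.uniform(size=size)
    # keep u strictly inside (0, 1) for the closed-form inverse
    u = np.clip(u, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)
    return quantile(spec, u)


def as_scipy(spec: FamilySpec):
    """Frozen ``scipy.stats`` distribution equivalent to ``spec``.

    scipy uses ``scale = 1/lam``; the shape parameter maps unchanged
    (``weibull_min`` ``c`` and ``fisk`` ``c`` are both ``beta``).
    """
    if spec.family == "exponential":
        return stats.expon(scale=1.0 / spec.lam)
    if spec.family == "weibull":
        return stats.weibull_min(spec.beta, scale=1.0 / spec.lam)
    return stats.fisk(spec.beta, scale=1.0 / spec.lam)
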