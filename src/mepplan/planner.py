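"""Single-subject trial-count planning.

How many trials does it take to pin down one subject's mean evoked-potential
amplitude?  The estimator is the cumulative (running) average of single-trial
peak-to-peak amplitudes, and the planning question is answered by the
coefficient of variation across trials, ``CV_trials = sigma_trials /
mu_trials``:

* ``n_opt_trials`` — the number of trials needed so that, with probability
  ``p_incl``, the running average lies within a relative error ``eta`` of the
  *true* mean: ``n_opt = (z * CV_trials / eta)**2``.
* ``error_single`` — the inverse view: the relative error implicitly accepted
  when averaging ``n`` trials, ``eta(n) = z * CV_trials / sqrt(n)``.

Two older, empirically motivated definitions are also provided because they
are still in circulation.  Both measure convergence of the running average to
the *sample* average of the ``n_max`` trials actually collected, and are
therefore bounded by — and largely determined by — ``n_max``:

* ``n_opt_ci`` — inclusion within a confidence interval of the sample mean;
  depends only on ``n_max`` and two critical values, never on variability.
* ``n_opt_pctdiff`` — inclusion within a percent difference of the sample
  mean; converges to ``n_opt_trials`` as ``n_max -> inf``.

Reports should label these two "n_max-bounded (deprecated definitions)".

All operations return unrounded real values; converting to an integer trial
count is an explicit separate step (:func:`round_count`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Union

from scipy.stats import norm

__all__ = [
    "DomainError",
    "InclusionSpec",
    "TrialStats",
    "RoundingPolicy",
    "critical_value",
    "n_opt_ci",
    "n_opt_pctdiff",
    "n_opt_trials",
    "error_single",
    "round_count",
]


class DomainError(ValueError):
    """A parameter is outside the domain where the planning formula is defined."""


def critical_value(p_incl: float) -> float:
    """Two-sided standard-normal critical value for an inclusion probability.

    Returns the ``1 - (1 - p_incl)/2`` quantile of N(0, 1), i.e. the ``z``
    such that a standard-normal variate falls in ``[-z, z]`` with probability
    ``p_incl``.  ``p_incl = 0.95`` gives the familiar 1.960.
    """
    if not 0.0 < p_incl < 1.0:
        raise DomainError(f"p_incl must be in (0, 1), got {p_incl}")
    return float(norm.ppf(1.0 - (1.0 - p_incl) / 2.0))


@dataclass(frozen=True)
class InclusionSpec:
    """An inclusion probability and its two-sided normal critical value.

    ``p_incl`` is the probability that the estimate falls within the stated
    relative error of the truth; ``alpha = 1 - p_incl``; ``z`` is the
    ``1 - alpha/2`` standard-normal quantile.
    """

    p_incl: float
    alpha: float = field(init=False)
    z: float = field(init=False)

    def __post_init__(self) -> None:
        z = critical_value(self.p_incl)  # validates p_incl
        object.__setattr__(self, "alpha", 1.0 - self.p_incl)
        object.__setattr__(self, "z", z)

    @classmethod
    def from_z(cls, z: float) -> "InclusionSpec":
        """Build the spec from a critical value (e.g. the 'golden' z = 2.493)."""
        if z <= 0:
            raise DomainError(f"critical value must be positive, got {z}")
        p_incl = float(2.0 * norm.cdf(z) - 1.0)
        return cls(p_incl=p_incl)


@dataclass(frozen=True)
class TrialStats:
    """Within-subject amplitude statistics: mean, SD and CV across trials (mV)."""

    mu_trials: float
    sigma_trials: float
    cv_trials: float = field(init=False)

    def __post_init__(self) -> None:
        if self.mu_trials <= 0:
            raise DomainError(f"mu_trials must be positive, got {self.mu_trials}")
        if self.sigma_trials < 0:
            raise DomainError(f"sigma_trials must be >= 0, got {self.sigma_trials}")
        object.__setattr__(self, "cv_trials", self.sigma_trials / self.mu_trials)


RoundingMode = Literal["raw", "ceil", "nearest"]


@dataclass(frozen=True)
class RoundingPolicy:
    """How to turn a real-valued count into a reportable one.

    ``raw`` passes the value through; ``ceil`` (the default in reports) rounds
    up so the planned count is guaranteed to meet the error bound; ``nearest``
    rounds half away from zero, the convention behind some published counts.
    """

    mode: RoundingMode = "ceil"

    def __post_init__(self) -> None:
        if self.mode not in ("raw", "ceil", "nearest"):
            raise DomainError(f"unknown rounding mode {self.mode!r}")


def round_count(x: float, policy: Union[RoundingPolicy, RoundingMode] = "ceil") -> float:
    """Apply a rounding policy to a non-negative real count."""
    if isinstance(policy, str):
        policy = RoundingPolicy(policy)
    if x < 0:
        raise DomainError(f"count must be >= 0, got {x}")
    if policy.mode == "raw" or math.isinf(x):
        return x
    # snap to 9 decimals first so counts that are integers up to floating-point
    # round-off (e.g. 196.00000000000003) do not get ceil'd one unit too high
    x = round(x, 9)
    if policy.mode == "ceil":
        return float(math.ceil(x))
    # nearest, halves away from zero (round(18.5) -> 19, not banker's 18)
    return float(math.floor(x + 0.5))


def _z(p_incl: float) -> float:
    return critical_value(p_incl)


def n_opt_ci(n_max: float, alpha_ci: float = 0.05, p_incl: float | None = None,
             z_incl: float | None = None) -> float:
    """n_max-bounded trial count from the confidence-interval inclusion rule.

    ``n_max / (1 + (z_ci / z_incl)**2)`` where ``z_ci`` is the critical value
    of the confidence interval around the sample mean and ``z_incl`` the one
    set by the inclusion probability.  Strictly less than ``n_max`` and —
    the deprecated definition's flaw — independent of any variability.

    Either ``p_incl`` or ``z_incl`` must be given.
    """
    if n_max < 1:
        raise DomainError(f"n_max must be >= 1, got {n_max}")
    if not 0.0 < alpha_ci < 1.0:
        raise DomainError(f"alpha_ci must be in (0, 1), got {alpha_ci}")
    if (p_incl is None) == (z_incl is None):
        raise DomainError("give exactly one of p_incl or z_incl")
    z_i = _z(p_incl) if z_incl is None else float(z_incl)
    if z_i <= 0:
        raise DomainError(f"z_incl must be positive, got {z_incl}")
    z_ci = _z(1.0 - alpha_ci)
    return n_max / (1.0 + (z_ci / z_i) ** 2)


def n_opt_pctdiff(n_max: float, stats: TrialStats, eta: float,
                  p_incl: float | None = None, z_incl: float | None = None) -> float:
    """n_max-bounded trial count from the percent-difference inclusion rule.

    ``1 / (1/n_max + (eta*mu / (z*sigma))**2)``.  Uses the trial-to-trial
    variability but remains capped by ``n_max``; its ``n_max -> inf`` limit is
    :func:`n_opt_trials`.  Zero variability means no averaging is needed (0).
    """
    if n_max < 1:
        raise DomainError(f"n_max must be >= 1, got {n_max}")
    if eta <= 0:
        raise DomainError(f"eta must be positive, got {eta}")
    if (p_incl is None) == (z_incl is None):
        raise DomainError("give exactly one of p_incl or z_incl")
    z = _z(p_incl) if z_incl is None else float(z_incl)
    if stats.sigma_trials == 0.0:
        return 0.0
    term = (eta * stats.mu_trials / (z * stats.sigma_trials)) ** 2
    return 1.0 / (1.0 / n_max + term)


def n_opt_trials(cv_trials: float, eta: float, p_incl: float = 0.95) -> float:
    """Trials needed to estimate a single subject's mean within ``eta``.

    ``(z * CV_trials / eta)**2`` — quadratic in the within-subject CV and in
    the reciprocal of the acceptable relative error, and, unlike the
    deprecated definitions, not bounded by the number of trials collected.
    """
    if eta <= 0:
        raise DomainError(f"eta must be positive, got {eta}")
    if cv_trials < 0:
        raise DomainError(f"cv_trials must be >= 0, got {cv_trials}")
    return (critical_value(p_incl) * cv_trials / eta) ** 2


def error_single(n: float, cv_trials: float, p_incl: float = 0.95) -> float:
    """Relative error implicitly accepted when averaging ``n`` trials.

    ``eta(n) = z * CV_trials / sqrt(n)``; the exact inverse of
    :func:`n_opt_trials`.  ``n = inf`` returns 0.
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    if cv_trials < 0:
        raise DomainError(f"cv_trials must be >= 0, got {cv_trials}")
    if math.isinf(n):
        return 0.0
    return critical_value(p_incl) * cv_trials / math.sqrt(n)
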