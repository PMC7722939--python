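"""Population-level estimation error, power, and reliability attenuation.

The observed variance of per-subject mean amplitudes, when each subject
contributes ``n`` trials, decomposes into a true between-subject part and a
trial-noise part::

    sigma_subjects(n)**2 = sigma_subjects**2 + sigma_trials**2 / n

Everything in this module follows from that decomposition:

* the relative error of the population mean as a function of the number of
  subjects ``N`` and trials ``n`` (:func:`error_population_n`);
* the t statistic and required sample size of a paired (or, with ``r = 0``,
  equal-N unpaired) comparison as a joint function of ``N`` and ``n``
  (:func:`t_statistic`, :func:`sample_size`);
* the attenuation of test-retest Pearson correlation by finite trial counts,
  and its classical disattenuation correction (:func:`reliability_at_n`,
  :func:`disattenuate`).

``n = math.inf`` is accepted everywhere and yields the analytic
infinite-trials limit.  Equal variances across the two compared populations
are assumed throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

from .planner import DomainError, critical_value

__all__ = [
    "DegenerateDecompositionError",
    "SubjectPopulation",
    "PairedComparison",
    "PowerSpec",
    "DisattenuatedR",
    "error_population",
    "sigma_subjects_at_n",
    "asymptotic_sigma_subjects",
    "error_population_n",
    "t_statistic",
    "sample_size",
    "reliability_at_n",
    "disattenuate",
]


class DegenerateDecompositionError(ValueError):
    """Observed between-subject spread is fully attributable to trial noise."""


def _noise_var(sigma_trials: float, n: float) -> float:
    """Trial-noise contribution ``sigma_trials**2 / n`` with ``n = inf`` -> 0."""
    if n < 1:
        raise DomainError(f"n must be >= 1 (or inf), got {n}")
    if math.isinf(n):
        return 0.0
    return sigma_trials**2 / n


@dataclass(frozen=True)
class SubjectPopulation:
    """Population parameters: mean, asymptotic between-subject SD, pooled
    within-subject SD (all mV), and optionally the between-subject CV at a
    stated trial count."""

    mu_subjects: float
    sigma_subjects: float
    sigma_trials: float
    cv_subjects: float | None = None

    def __post_init__(self) -> None:
        if self.mu_subjects <= 0:
            raise DomainError(f"mu_subjects must be positive, got {self.mu_subjects}")
        if self.sigma_subjects < 0 or self.sigma_trials < 0:
            raise DomainError("standard deviations must be >= 0")


@dataclass(frozen=True)
class PairedComparison:
    """Two population means with shared variances and asymptotic correlation.

    ``r`` is the correlation between the two measures that would be observed
    with infinitely many trials per measure; ``r = 0`` encodes the equal-N,
    equal-variance unpaired design.
    """

    mu1: float
    mu2: float
    sigma_subjects: float
    sigma_trials: float
    r: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_subjects < 0 or self.sigma_trials < 0:
            raise DomainError("standard deviations must be >= 0")
        if not -1.0 <= self.r <= 1.0:
            raise DomainError(f"r must be in [-1, 1], got {self.r}")


@dataclass(frozen=True)
class PowerSpec:
    """Two-sided type-I error, type-II error, and the resulting z-sum.

    ``z_sum = z_{1-alpha/2} + z_{1-beta}`` is computed from the inverse normal
    CDF; pass ``z_sum`` explicitly to reproduce published numbers computed
    with a two-decimal 2.80 (multiplier 15.68) convention.
    """

    alpha: float = 0.05
    beta: float = 0.20
    z_sum: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0 or not 0.0 < self.beta < 1.0:
            raise DomainError("alpha and beta must be in (0, 1)")
        if self.z_sum is None:
            z = critical_value(1.0 - self.alpha) + _z_one_sided(1.0 - self.beta)
            object.__setattr__(self, "z_sum", float(z))
        elif self.z_sum <= 0:
            raise DomainError(f"z_sum must be positive, got {self.z_sum}")


def _z_one_sided(p: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(p))


def error_population(N: float, cv_subjects: float, p_incl: float = 0.95) -> float:
    """Relative error of the population mean from ``N`` subjects.

    ``eta(N) = z * CV_subjects / sqrt(N)`` — the subject-level analogue of the
    single-subject error formula.
    """
    if N < 1:
        raise DomainError(f"N must be >= 1, got {N}")
    if cv_subjects < 0:
        raise DomainError(f"cv_subjects must be >= 0, got {cv_subjects}")
    if math.isinf(N):
        return 0.0
    return critical_value(p_incl) * cv_subjects / math.sqrt(N)


def sigma_subjects_at_n(pop: SubjectPopulation, n: float) -> float:
    """Observed between-subject SD when each subject averages ``n`` trials."""
    return math.sqrt(pop.sigma_subjects**2 + _noise_var(pop.sigma_trials, n))


def asymptotic_sigma_subjects(sigma_obs_at_n: float, sigma_trials: float, n: float) -> float:
    """Invert the variance decomposition: true between-subject SD from the
    observed one.

    Raises :class:`DegenerateDecompositionError` when the observed variance
    does not exceed the trial-noise term, i.e. when the data carry no evidence
    of between-subject spread.
    """
    noise = _noise_var(sigma_trials, n)
    resid = sigma_obs_at_n**2 - noise
    if resid <= 0:
        raise DegenerateDecompositionError(
            f"observed variance {sigma_obs_at_n**2:.6g} <= trial-noise variance "
            f"{noise:.6g}: between-subject spread is indistinguishable from noise"
        )
    return math.sqrt(resid)


def error_population_n(pop: SubjectPopulation, N: float, n: float,
                       p_incl: float = 0.95) -> float:
    """Relative error of the population mean with ``N`` subjects x ``n`` trials.

    ``eta(N, n) = z * sqrt(sigma_s**2 + sigma_t**2/n) / (mu_s * sqrt(N))``.
    At ``n = inf`` this equals :func:`error_population` with
    ``CV_subjects = sigma_s / mu_s``.
    """
    if N < 1:
        raise DomainError(f"N must be >= 1, got {N}")
    z = critical_value(p_incl)
    return z * sigma_subjects_at_n(pop, n) / (pop.mu_subjects * math.sqrt(N))


def t_statistic(cmp: PairedComparison, N: float, n: float) -> float:
    """Expected t statistic of the paired comparison with ``N`` subjects and
    ``n`` trials per measure.

    ``t = (mu1 - mu2) / sqrt(2 [sigma_s**2 (1 - r) + sigma_t**2 / n] / N)``.
    With ``r = 0`` this is the equal-N unpaired t with per-group variance
    ``sigma_s**2 + sigma_t**2 / n``.
    """
    if N < 2:
        raise DomainError(f"N must be >= 2, got {N}")
    var = cmp.sigma_subjects**2 * (1.0 - cmp.r) + _noise_var(cmp.sigma_trials, n)
    if var <= 0:
        raise DegenerateDecompositionError(
            "zero denominator: no between-subject or trial variance remains"
        )
    return (cmp.mu1 - cmp.mu2) / math.sqrt(2.0 * var / N)


def sample_size(cmp: PairedComparison, spec: PowerSpec | None = None,
                n: float = math.inf) -> float:
    """Subjects required to detect ``mu1 - mu2`` with the stated power.

    ``N_opt(n) = 2 [sigma_s**2 (1 - r) + sigma_t**2/n] * z_sum**2 / delta**2``.
    Returned unrounded; reported counts conventionally use ceil.  With the
    default alpha = 0.05, beta = 0.20 the multiplier ``2 * z_sum**2`` is
    approximately 15.7 (15.68 with the printed two-decimal z-sum).
    """
    spec = spec or PowerSpec()
    delta = cmp.mu1 - cmp.mu2
    if delta == 0:
        raise DomainError("mu1 == mu2: required sample size is infinite")
    var = cmp.sigma_subjects**2 * (1.0 - cmp.r) + _noise_var(cmp.sigma_trials, n)
    return 2.0 * var * spec.z_sum**2 / delta**2


def reliability_at_n(r: float, sigma_subjects: float, sigma_trials: float,
                     n: float) -> float:
    """Test-retest Pearson correlation attenuated by finite trial counts.

    ``r(n) = r * sigma_s**2 / (sigma_s**2 + sigma_t**2 / n)``; tends to the
    asymptotic ``r`` as ``n -> inf`` and can never exceed it in magnitude.
    """
    if not -1.0 <= r <= 1.0:
        raise DomainError(f"r must be in [-1, 1], got {r}")
    noise = _noise_var(sigma_trials, n)
    denom = sigma_subjects**2 + noise
    if denom == 0.0:
        return r  # no variance at all: attenuation undefined, no-op
    if sigma_subjects == 0.0:
        return 0.0
    return r * sigma_subjects**2 / denom


class DisattenuatedR(NamedTuple):
    """A disattenuated correlation and whether it landed inside [-1, 1]."""

    value: float
    in_bounds: bool


def disattenuate(r_n: float, sigma_obs_at_n: float, sigma_trials: float,
                 n: float) -> DisattenuatedR:
    """Classical correction for attenuation.

    ``r = r(n) * sigma_obs(n)**2 / (sigma_obs(n)**2 - sigma_t**2/n)`` — the
    algebraic inverse of :func:`reliability_at_n` given the *observed*
    between-subject SD.  On noisy inputs the estimator can leave [-1, 1];
    the value is returned unclipped with ``in_bounds`` set accordingly.
    """
    noise = _noise_var(sigma_trials, n)
    resid = sigma_obs_at_n**2 - noise
    if resid <= 0:
        raise DegenerateDecompositionError(
            f"observed variance {sigma_obs_at_n**2:.6g} <= trial-noise variance "
            f"{noise:.6g}: disattenuation undefined"
        )
    value = r_n * sigma_obs_at_n**2 / resid
    return DisattenuatedR(value=value, in_bounds=-1.0 <= value <= 1.0)
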