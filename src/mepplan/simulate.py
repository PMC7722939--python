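"""Moment-matched lognormal Monte Carlo engine.

Evoked-potential amplitudes are positive and right-skewed, so the analytic
planning formulas — which only assume approximate normality of *averages* —
are stress-tested here against lognormal data.  A lognormal with arithmetic
mean ``m`` and SD ``s`` is the exponential of a normal with::

    log_mean = log(m**2 / sqrt(m**2 + s**2))
    log_var  = log(1 + s**2 / m**2)

so targets are matched exactly, not fitted.  Correlated pairs of subject
means come from the exponential of a bivariate normal whose log-scale
covariance is ``log(1 + r * sigma_s**2 / (mu1 * mu2))``.

The three ``simulate_*`` functions reproduce the validation protocols:
percentile error curves for a single subject's running mean, for a
population mean, and empirical t curves for paired/unpaired comparisons
(with the c4 small-sample correction applied to SD estimates).  Each is
deterministic under its configured seed.  :func:`generate_fixture` draws a
subjects x trials amplitude matrix with this hierarchy and is the synthetic
stand-in for a real recording session used throughout the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .planner import DomainError
from .population import PairedComparison, SubjectPopulation

__all__ = [
    "LognormalSpec",
    "BivariateLognormalSpec",
    "SimConfig",
    "ErrorCurve",
    "lognormal_spec",
    "bivariate_lognormal_spec",
    "c4",
    "simulate_single_subject_curve",
    "simulate_population_curve",
    "simulate_t_curve",
    "generate_fixture",
    "generate_paired_fixture",
]


@dataclass(frozen=True)
class LognormalSpec:
    """Log-scale parameters of a lognormal with given arithmetic mean and SD."""

    target_mean: float
    target_sd: float
    log_mean: float
    log_var: float

    @property
    def skewness(self) -> float:
        """Analytic skewness ``(e**v + 2) * sqrt(e**v - 1)`` of the marginal."""
        ev = math.exp(self.log_var)
        return (ev + 2.0) * math.sqrt(ev - 1.0)


def lognormal_spec(mean: float, sd: float) -> LognormalSpec:
    """Moment-match a lognormal to an arithmetic mean (mV) and SD (mV).

    ``sd = 0`` degenerates to a point mass at ``mean``.
    """
    if mean <= 0:
        raise DomainError(f"mean must be positive, got {mean}")
    if sd < 0:
        raise DomainError(f"sd must be >= 0, got {sd}")
    log_mean = math.log(mean**2 / math.sqrt(mean**2 + sd**2))
    log_var = math.log(1.0 + sd**2 / mean**2)
    return LognormalSpec(target_mean=mean, target_sd=sd,
                         log_mean=log_mean, log_var=log_var)


@dataclass(frozen=True)
class BivariateLognormalSpec:
    """Two lognormal marginals plus their log-scale covariance."""

    marginal1: LognormalSpec
    marginal2: LognormalSpec
    log_cov: float

    @property
    def log_mean(self) -> np.ndarray:
        return np.array([self.marginal1.log_mean, self.marginal2.log_mean])

    @property
    def log_cov_matrix(self) -> np.ndarray:
        return np.array([
            [self.marginal1.log_var, self.log_cov],
            [self.log_cov, self.marginal2.log_var],
        ])


def bivariate_lognormal_spec(mean1: float, mean2: float, sd: float,
                             r: float) -> BivariateLognormalSpec:
    """Moment-match a correlated pair of lognormal subject-mean distributions.

    Shared between-subject SD ``sd`` and asymptotic correlation ``r``; the
    log-scale covariance is ``log(1 + r * sd**2 / (mean1 * mean2))``.
    """
    m1 = lognormal_spec(mean1, sd)
    m2 = lognormal_spec(mean2, sd)
    log_cov = math.log(1.0 + r * sd**2 / (mean1 * mean2))
    spec = BivariateLognormalSpec(marginal1=m1, marginal2=m2, log_cov=log_cov)
    cov = spec.log_cov_matrix
    # positive semi-definite check for the 2x2 log-scale covariance
    if cov[0, 0] * cov[1, 1] - log_cov**2 < -1e-15 or cov[0, 0] < 0 or cov[1, 1] < 0:
        raise DomainError("log-scale covariance matrix is not positive semi-definite")
    return spec


def c4(N: float) -> float:
    """Small-sample bias correction for the sample SD (series form).

    ``1 - 1/(4N) - 7/(32 N**2) - 19/(128 N**3)``; dividing an n-1 sample SD
    by this factor removes most of its downward bias.  Tends to 1 from below.
    """
    if N < 2:
        raise DomainError(f"N must be >= 2, got {N}")
    return 1.0 - 1.0 / (4.0 * N) - 7.0 / (32.0 * N**2) - 19.0 / (128.0 * N**3)


@dataclass(frozen=True)
class SimConfig:
    """Replicate count, trial-axis length, percentile convention, and seed."""

    n_replicates: int = 10_000
    n_trials_max: int = 100
    seed: int = 0
    percentile: float = 0.95

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be >= 1")
        if self.n_trials_max < 1:
            raise DomainError("n_trials_max must be >= 1")
        if not 0.0 < self.percentile < 1.0:
            raise DomainError("percentile must be in (0, 1)")


@dataclass(frozen=True)
class ErrorCurve:
    """A quantity indexed by the number of trials 1..n_max.

    ``values`` holds relative errors for the estimation protocols and t
    statistics for the hypothesis-testing protocol.
    """

    n_trials: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.n_trials)
        v = np.asarray(self.values, dtype=float)
        if n.shape != v.shape:
            raise DomainError("n_trials and values must have equal length")
        if n.size and np.any(np.diff(n) <= 0):
            raise DomainError("n_trials must be strictly increasing")
        object.__setattr__(self, "n_trials", n)
        object.__setattr__(self, "values", v)


def _rng(seed: int, stream: int) -> np.random.Generator:
    """One generator per (seed, protocol) pair; replicates are vectorized rows."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _lognormal_draws(rng: np.random.Generator, mean: np.ndarray | float,
                     sd: float, size: tuple[int, ...]) -> np.ndarray:
    """Draws with per-element arithmetic mean ``mean`` and common SD ``sd`` (mV)."""
    mean = np.asarray(mean, dtype=float)
    if sd == 0.0:
        return np.broadcast_to(mean, size).copy()
    var_ratio = sd**2 / mean**2
    log_var = np.log1p(var_ratio)
    log_mean = np.log(mean) - 0.5 * log_var
    return np.exp(log_mean + np.sqrt(log_var) * rng.standard_normal(size))


def simulate_single_subject_curve(cv: float, cfg: SimConfig) -> ErrorCurve:
    """Empirical relative-error curve of the running mean for one subject.

    Replicate subjects draw i.i.d. lognormal trials with mean 1 mV and SD
    ``cv`` mV; for each n the configured percentile of ``|running mean -
    true mean| / true mean`` across replicates estimates the relative error.
    """
    if cv < 0:
        raise DomainError(f"cv must be >= 0, got {cv}")
    ns = np.arange(1, cfg.n_trials_max + 1)
    if cv == 0.0:
        return ErrorCurve(n_trials=ns, values=np.zeros_like(ns, dtype=float))
    rng = _rng(cfg.seed, stream=1)
    true_mean = 1.0
    trials = _lognormal_draws(rng, true_mean, cv * true_mean,
                              (cfg.n_replicates, cfg.n_trials_max))
    cum_mean = np.cumsum(trials, axis=1) / ns
    abs_err = np.abs(cum_mean - true_mean) / true_mean
    eta = np.quantile(abs_err, cfg.percentile, axis=0)
    return ErrorCurve(n_trials=ns, values=eta)


def simulate_population_curve(pop: SubjectPopulation, N: int,
                              cfg: SimConfig) -> ErrorCurve:
    """Empirical relative-error curve of the population mean.

    Hierarchy: subject means lognormal(mu_s, sigma_s); trials lognormal around
    each subject's mean with SD sigma_t.  The percentile is taken across
    replicate populations of the absolute error of the running population
    mean, divided by the true population mean.
    """
    ns = np.arange(1, cfg.n_trials_max + 1)
    if pop.sigma_subjects == 0.0 and pop.sigma_trials == 0.0:
        return ErrorCurve(n_trials=ns, values=np.zeros_like(ns, dtype=float))
    rng = _rng(cfg.seed, stream=2)
    errors = np.empty((cfg.n_replicates, cfg.n_trials_max))
    chunk = max(1, int(5e6 / (N * cfg.n_trials_max)))
    for start in range(0, cfg.n_replicates, chunk):
        stop = min(start + chunk, cfg.n_replicates)
        R = stop - start
        subj_means = _lognormal_draws(rng, pop.mu_subjects, pop.sigma_subjects, (R, N))
        trials = _lognormal_draws(rng, subj_means[..., None], pop.sigma_trials,
                                  (R, N, cfg.n_trials_max))
        cum_mean = np.cumsum(trials, axis=2) / ns  # per-subject running mean
        pop_mean = cum_mean.mean(axis=1)  # across subjects
        errors[start:stop] = np.abs(pop_mean - pop.mu_subjects) / pop.mu_subjects
    eta = np.quantile(errors, cfg.percentile, axis=0)
    return ErrorCurve(n_trials=ns, values=eta)


def _paired_subject_means(rng: np.random.Generator, cmp: PairedComparison,
                          R: int, N: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw (R, N) correlated subject-mean pairs for the two measures."""
    spec = bivariate_lognormal_spec(cmp.mu1, cmp.mu2, cmp.sigma_subjects, cmp.r)
    z = rng.standard_normal((R, N, 2))
    L = np.linalg.cholesky(spec.log_cov_matrix + 1e-18 * np.eye(2))
    logs = spec.log_mean + z @ L.T
    means = np.exp(logs)
    return means[..., 0], means[..., 1]


def simulate_t_curve(cmp: PairedComparison, N: int, cfg: SimConfig) -> ErrorCurve:
    """Empirical t curve of the paired comparison versus number of trials.

    For each replicate population pair, running per-subject means of the two
    measures are differenced; the mean and c4-corrected SD of the differences
    are averaged across replicates, then combined as ``t = mean / (sd /
    sqrt(N))``.  The ``r = 0`` path is the equal-N unpaired construction.
    """
    if N < 2:
        raise DomainError(f"N must be >= 2, got {N}")
    ns = np.arange(1, cfg.n_trials_max + 1)
    rng = _rng(cfg.seed, stream=3)
    sum_mean_d = np.zeros(cfg.n_trials_max)
    sum_sd_d = np.zeros(cfg.n_trials_max)
    chunk = max(1, int(4e6 / (2 * N * cfg.n_trials_max)))
    for start in range(0, cfg.n_replicates, chunk):
        stop = min(start + chunk, cfg.n_replicates)
        R = stop - start
        m1, m2 = _paired_subject_means(rng, cmp, R, N)
        t1 = _lognormal_draws(rng, m1[..., None], cmp.sigma_trials,
                              (R, N, cfg.n_trials_max))
        t2 = _lognormal_draws(rng, m2[..., None], cmp.sigma_trials,
                              (R, N, cfg.n_trials_max))
        d = (np.cumsum(t1, axis=2) - np.cumsum(t2, axis=2)) / ns
        sum_mean_d += d.mean(axis=1).sum(axis=0)
        sum_sd_d += (d.std(axis=1, ddof=1) / c4(N)).sum(axis=0)
    mean_d = sum_mean_d / cfg.n_replicates
    sd_d = sum_sd_d / cfg.n_replicates
    return ErrorCurve(n_trials=ns, values=mean_d / (sd_d / math.sqrt(N)))


def generate_fixture(pop: SubjectPopulation, N: int, n: int, seed: int):
    """Synthetic subjects x trials amplitude matrix (mV).

    Drawn with the population-curve hierarchy (lognormal subject means,
    lognormal trials around them); deterministic under ``seed``.  Returns a
    :class:`~mepplan.estimate.TrialMatrix`.
    """
    from .estimate import TrialMatrix

    if N < 1 or n < 1:
        raise DomainError("N and n must be >= 1")
    rng = _rng(seed, stream=4)
    subj_means = _lognormal_draws(rng, pop.mu_subjects, pop.sigma_subjects, (N,))
    trials = _lognormal_draws(rng, subj_means[:, None], pop.sigma_trials, (N, n))
    subjects = [f"S{i + 1:03d}" for i in range(N)]
    return TrialMatrix(subjects=subjects, trials=[row for row in trials])


def generate_paired_fixture(cmp: PairedComparison, N: int, n: int, seed: int):
    """Two synthetic trial matrices whose subject means share asymptotic
    correlation ``cmp.r`` — e.g. two sessions or two stimulus intensities.

    Returns a pair of :class:`~mepplan.estimate.TrialMatrix` with matched
    subject identifiers.
    """
    from .estimate import TrialMatrix

    if N < 1 or n < 1:
        raise DomainError("N and n must be >= 1")
    rng = _rng(seed, stream=5)
    m1, m2 = _paired_subject_means(rng, cmp, 1, N)
    t1 = _lognormal_draws(rng, m1[0][:, None], cmp.sigma_trials, (N, n))
    t2 = _lognormal_draws(rng, m2[0][:, None], cmp.sigma_trials, (N, n))
    subjects = [f"S{i + 1:03d}" for i in range(N)]
    return (TrialMatrix(subjects=subjects, trials=[row for row in t1]),
            TrialMatrix(subjects=subjects, trials=[row for row in t2]))
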