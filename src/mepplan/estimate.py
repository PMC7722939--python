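"""Estimate planning parameters from a subjects x trials amplitude matrix.

This is the workflow for turning a recorded session into the inputs of the
planning formulas: per-subject trial statistics, the pooled within-subject SD,
the observed and asymptotic between-subject SD (via the variance
decomposition), a split-half correlation as a lower bound on test-retest
reliability, and a planning report that rolls all of it up.

Trial order is taken as recorded — the split-half correlation compares the
mean of the first block of trials with the mean of the next block, so
shuffling would destroy its meaning.  Amplitudes are assumed stationary
within a session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .planner import DomainError, critical_value, error_single, n_opt_trials, round_count
from .population import (
    DegenerateDecompositionError,
    PairedComparison,
    PowerSpec,
    SubjectPopulation,
    asymptotic_sigma_subjects,
    error_population_n,
    sample_size,
)

__all__ = [
    "TrialMatrix",
    "SubjectSummary",
    "PopulationEstimate",
    "SplitHalfResult",
    "summarize_subjects",
    "estimate_population",
    "split_half_r",
    "planning_report",
]

#: trial counts at which report tables are evaluated (inf = asymptotic limit)
REPORT_TRIAL_GRID = (1, 5, 10, 20, 30, 40, 100, math.inf)


@dataclass
class TrialMatrix:
    """Ordered single-trial amplitudes (mV) per subject; may be ragged."""

    subjects: list[str]
    trials: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.subjects) != len(self.trials):
            raise DomainError("subjects and trials must have equal length")
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]
        for sid, t in zip(self.subjects, self.trials):
            if t.ndim != 1 or t.size == 0:
                raise DomainError(f"subject {sid!r}: trials must be a non-empty 1-D array")
            if np.any(t < 0) or not np.all(np.isfinite(t)):
                raise DomainError(f"subject {sid!r}: amplitudes must be finite and >= 0")

    @property
    def N(self) -> int:
        return len(self.subjects)

    @property
    def trial_counts(self) -> np.ndarray:
        return np.array([t.size for t in self.trials])

    @property
    def n(self) -> int:
        """Trials per subject; defined only for rectangular matrices."""
        counts = self.trial_counts
        if np.any(counts != counts[0]):
            raise DomainError("ragged matrix has no single trial count n")
        return int(counts[0])

    @property
    def is_rectangular(self) -> bool:
        counts = self.trial_counts
        return bool(np.all(counts == counts[0]))

    def to_tidy(self) -> pd.DataFrame:
        """One row per (subject, trial): subject_id, trial_index (1-based), amplitude_mv."""
        frames = [
            pd.DataFrame({
                "subject_id": sid,
                "trial_index": np.arange(1, t.size + 1),
                "amplitude_mv": t,
            })
            for sid, t in zip(self.subjects, self.trials)
        ]
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_tidy(cls, df: pd.DataFrame) -> "TrialMatrix":
        required = {"subject_id", "trial_index", "amplitude_mv"}
        missing = required - set(df.columns)
        if missing:
            raise DomainError(f"tidy table is missing columns: {sorted(missing)}")
        subjects, trials = [], []
        for sid, grp in df.groupby("subject_id", sort=False):
            grp = grp.sort_values("trial_index")
            subjects.append(str(sid))
            trials.append(grp["amplitude_mv"].to_numpy(dtype=float))
        return cls(subjects=subjects, trials=trials)

    @classmethod
    def from_wide(cls, df: pd.DataFrame) -> "TrialMatrix":
        """One row per subject, columns ``subject_id, trial_1..trial_n``.

        Trailing missing values allow ragged data.
        """
        if "subject_id" not in df.columns:
            raise DomainError("wide table needs a subject_id column")
        trial_cols = sorted(
            (c for c in df.columns if c.startswith("trial_")),
            key=lambda c: int(c.split("_", 1)[1]),
        )
        if not trial_cols:
            raise DomainError("wide table needs trial_1..trial_n columns")
        subjects, trials = [], []
        for _, row in df.iterrows():
            vals = row[trial_cols].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            subjects.append(str(row["subject_id"]))
            trials.append(vals)
        return cls(subjects=subjects, trials=trials)


@dataclass(frozen=True)
class SubjectSummary:
    """Per-subject trial statistics (mean/SD in mV)."""

    subject_id: str
    n_trials: int
    mean: float
    sd: float
    cv: float
    skewness: float


def summarize_subjects(data: TrialMatrix) -> list[SubjectSummary]:
    """Mean, SD (n-1), CV and bias-corrected skewness per subject.

    Every subject needs at least 2 trials; skewness needs 3 and is NaN below
    that.
    """
    out = []
    for sid, t in zip(data.subjects, data.trials):
        if t.size < 2:
            raise DomainError(f"subject {sid!r} has {t.size} trial(s); need >= 2")
        mean = float(t.mean())
        sd = float(t.std(ddof=1))
        cv = sd / mean if mean > 0 else math.nan
        # skewness needs >= 3 trials and some spread (undefined for constants)
        skew = float(sps.skew(t, bias=False)) if t.size >= 3 and sd > 0 else math.nan
        out.append(SubjectSummary(subject_id=sid, n_trials=int(t.size),
                                  mean=mean, sd=sd, cv=cv, skewness=skew))
    return out


@dataclass(frozen=True)
class PopulationEstimate:
    """Planning parameters extracted from a trial matrix (amplitudes in mV)."""

    mu_subjects: float
    sigma_subjects_at_n: float
    sigma_subjects_asymptotic: float
    sigma_trials_pooled: float
    cv_subjects: float
    cv_trials_mean: float
    cv_trials_range: tuple[float, float]
    n: float  # mean trials per subject (exact count when rectangular)
    N: int
    degenerate_decomposition: bool = False

    def as_population(self) -> SubjectPopulation:
        """The asymptotic-parameter view used by the planning formulas."""
        return SubjectPopulation(
            mu_subjects=self.mu_subjects,
            sigma_subjects=self.sigma_subjects_asymptotic,
            sigma_trials=self.sigma_trials_pooled,
            cv_subjects=self.cv_subjects,
        )


def estimate_population(data: TrialMatrix) -> PopulationEstimate:
    """Population planning parameters from per-subject statistics.

    * ``mu_subjects``: mean of subject means.
    * ``sigma_subjects_at_n``: SD (n-1) of subject means — the observed
      between-subject spread at the recorded trial count.
    * ``sigma_trials_pooled``: square root of the trial-count-weighted mean of
      per-subject variances (plain mean for rectangular data).
    * ``sigma_subjects_asymptotic``: observed spread with the trial-noise
      variance ``sigma_trials**2 / n`` removed.  If nothing remains after the
      subtraction the asymptotic SD is reported as 0 with
      ``degenerate_decomposition=True``.
    """
    if data.N < 2:
        raise DomainError(f"need >= 2 subjects, got {data.N}")
    summaries = summarize_subjects(data)
    means = np.array([s.mean for s in summaries])
    variances = np.array([s.sd**2 for s in summaries])
    counts = data.trial_counts.astype(float)

    mu_subjects = float(means.mean())
    sigma_obs = float(means.std(ddof=1))
    pooled_var = float(np.average(variances, weights=counts))
    sigma_trials = math.sqrt(pooled_var)
    n_mean = float(counts.mean())

    degenerate = False
    try:
        sigma_asym = asymptotic_sigma_subjects(sigma_obs, sigma_trials, n_mean)
    except DegenerateDecompositionError:
        sigma_asym = 0.0
        degenerate = True

    cvs = np.array([s.cv for s in summaries])
    return PopulationEstimate(
        mu_subjects=mu_subjects,
        sigma_subjects_at_n=sigma_obs,
        sigma_subjects_asymptotic=sigma_asym,
        sigma_trials_pooled=sigma_trials,
        cv_subjects=sigma_obs / mu_subjects if mu_subjects > 0 else math.nan,
        cv_trials_mean=float(cvs.mean()),
        cv_trials_range=(float(cvs.min()), float(cvs.max())),
        n=n_mean,
        N=data.N,
        degenerate_decomposition=degenerate,
    )


@dataclass(frozen=True)
class SplitHalfResult:
    """Split-half correlation across subjects with per-subject diagnostics.

    ``leave_one_out`` holds the correlation recomputed with each subject
    removed in turn — an outlier check that is deliberately left to the
    analyst rather than automated.
    """

    r: float
    block: int
    N: int
    first_block_means: np.ndarray
    second_block_means: np.ndarray
    leave_one_out: np.ndarray


def split_half_r(data: TrialMatrix, block: int) -> SplitHalfResult:
    """Pearson correlation between first-block and second-block subject means.

    The mean of trials ``1..block`` is correlated, across subjects, with the
    mean of trials ``block+1..2*block``.  Because each half uses only
    ``block`` trials the result is an attenuated (lower-bound) estimate of the
    asymptotic correlation; disattenuate with
    :func:`mepplan.population.disattenuate` if needed.
    """
    if block < 1:
        raise DomainError(f"block must be >= 1, got {block}")
    if data.N < 3:
        raise DomainError(f"need >= 3 subjects for a split-half correlation, got {data.N}")
    short = [sid for sid, t in zip(data.subjects, data.trials) if t.size < 2 * block]
    if short:
        raise DomainError(
            f"subjects with fewer than {2 * block} trials: {short}"
        )
    first = np.array([t[:block].mean() for t in data.trials])
    second = np.array([t[block:2 * block].mean() for t in data.trials])
    r = float(np.corrcoef(first, second)[0, 1])
    loo = np.array([
        float(np.corrcoef(np.delete(first, i), np.delete(second, i))[0, 1])
        for i in range(data.N)
    ])
    return SplitHalfResult(r=r, block=block, N=data.N,
                           first_block_means=first, second_block_means=second,
                           leave_one_out=loo)


def planning_report(est: PopulationEstimate, eta: float = 0.1,
                    p_incl: float = 0.95, power: PowerSpec | None = None,
                    delta_spec: tuple[float, float] | None = None,
                    r: float | None = None,
                    conservative_halved: bool = False,
                    trial_grid: Sequence[float] = REPORT_TRIAL_GRID) -> dict:
    """Roll an estimate up into planning tables.

    Sections of the returned dict:

    * ``single_subject``: trials needed per subject (mean CV and its range)
      for the target error ``eta``, plus the error actually achieved at the
      recorded trial count.
    * ``population_error``: relative error of the population mean over
      ``trial_grid`` at the recorded N.
    * ``sample_size`` (when a detectable difference is supplied): subjects
      needed over ``trial_grid``, for the within-subject design (requires
      ``r``) and the between-subject design (r = 0).

    ``delta_spec`` gives the two condition means directly.  Alternatively
    ``conservative_halved=True`` constructs them pessimistically from the
    estimate itself: ``mu1`` is the lower confidence limit of the estimated
    population mean and ``mu2 = mu1 / 2``.
    """
    if est.mu_subjects <= 0:
        raise DomainError("population mean must be positive")
    z = critical_value(p_incl)
    pop = est.as_population()

    cv_lo, cv_hi = est.cv_trials_range
    single = {
        "cv_trials_mean": est.cv_trials_mean,
        "cv_trials_range": [cv_lo, cv_hi],
        "n_opt_raw": n_opt_trials(est.cv_trials_mean, eta, p_incl),
        "n_opt": round_count(n_opt_trials(est.cv_trials_mean, eta, p_incl), "ceil"),
        "n_opt_range": [
            round_count(n_opt_trials(cv_lo, eta, p_incl), "ceil"),
            round_count(n_opt_trials(cv_hi, eta, p_incl), "ceil"),
        ],
        "error_at_recorded_n": error_single(est.n, est.cv_trials_mean, p_incl),
        "error_at_recorded_n_range": [
            error_single(est.n, cv_lo, p_incl),
            error_single(est.n, cv_hi, p_incl),
        ],
    }

    pop_error = {
        "N": est.N,
        "trials": list(trial_grid),
        "eta": [error_population_n(pop, est.N, ni, p_incl) for ni in trial_grid],
    }

    report: dict = {
        "inputs": {
            "eta": eta,
            "p_incl": p_incl,
            "z": z,
            "estimate": {
                "mu_subjects": est.mu_subjects,
                "sigma_subjects_at_n": est.sigma_subjects_at_n,
                "sigma_subjects_asymptotic": est.sigma_subjects_asymptotic,
                "sigma_trials_pooled": est.sigma_trials_pooled,
                "cv_subjects": est.cv_subjects,
                "n": est.n,
                "N": est.N,
            },
        },
        "single_subject": single,
        "population_error": pop_error,
        "warnings": (["degenerate variance decomposition: asymptotic "
                      "between-subject SD reported as 0"]
                     if est.degenerate_decomposition else []),
    }

    if delta_spec is None and conservative_halved:
        eta_hat = error_population_n(pop, est.N, est.n, p_incl)
        mu1 = est.mu_subjects * (1.0 - eta_hat)
        delta_spec = (mu1, mu1 / 2.0)

    if delta_spec is not None:
        mu1, mu2 = delta_spec
        power = power or PowerSpec()
        designs: dict = {}
        if r is not None:
            cmp_within = PairedComparison(mu1=mu1, mu2=mu2,
                                          sigma_subjects=est.sigma_subjects_asymptotic,
                                          sigma_trials=est.sigma_trials_pooled, r=r)
            designs["within"] = {
                "r": r,
                "trials": list(trial_grid),
                "N_opt": [round_count(sample_size(cmp_within, power, ni), "ceil")
                          for ni in trial_grid],
            }
        cmp_between = PairedComparison(mu1=mu1, mu2=mu2,
                                       sigma_subjects=est.sigma_subjects_asymptotic,
                                       sigma_trials=est.sigma_trials_pooled, r=0.0)
        designs["between"] = {
            "r": 0.0,
            "trials": list(trial_grid),
            "N_opt": [round_count(sample_size(cmp_between, power, ni), "ceil")
                      for ni in trial_grid],
        }
        report["sample_size"] = {
            "mu1": mu1,
            "mu2": mu2,
            "alpha": power.alpha,
            "beta": power.beta,
            "z_sum": power.z_sum,
            "designs": designs,
        }
    elif r is not None and delta_spec is None and not conservative_halved:
        raise DomainError("a paired design needs a detectable difference: "
                          "pass delta_spec or conservative_halved=True")

    return report
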