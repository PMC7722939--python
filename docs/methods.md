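# Methods

## Model and assumptions

`mepplan` treats a single-trial evoked-potential amplitude as a stochastic
variable: within subject *s* trials are i.i.d. with mean μ_trials(s) and SD
σ_trials (no drift, autocorrelation, or attention/arousal modelling —
stationarity within a session is assumed); subject means vary around the
population mean μ_subjects with asymptotic between-subject SD σ_subjects.
Averaging n trials per subject leaves trial noise in the observed
between-subject variance,

    σ²_subjects(n) = σ²_subjects + σ²_trials/n,

which is the single identity behind all the planning formulas: estimation
error of a single-subject mean (z·CV_trials/√n), of a population mean
(z·√(σ²_s+σ²_t/n)/(μ_s√N)), the expected paired/unpaired t statistic and the
required sample size (via σ²_s(1−r)+σ²_t/n, with r the asymptotic correlation
between the two measures), and the attenuation of test-retest correlations
(r(n) = r·σ²_s/(σ²_s+σ²_t/n)) together with its classical disattenuation
correction.

The formulas do **not** assume amplitudes are normal — only that sample
*means* are approximately normal (central limit theorem) and, for the paired
comparison, that the two populations share variances (equal-variance design is
hard-coded; unequal variances are out of scope). No small-sample t or exact
noncentral-t correction is applied: the sample-size formula is the
normal-approximation one, which is what makes its published tables
reproducible. Pearson's r is the reliability statistic; ICC variants are not
implemented.

## Parameters, units, defaults

- Amplitudes, means and SDs are in mV throughout; CVs, correlations and
  relative errors are dimensionless.
- `p_incl` (default 0.95): probability that the estimate lands within the
  stated relative error; its two-sided normal critical value is always
  computed from the inverse normal CDF, never from a lookup table, so printed
  two-decimal values (1.96, 2.80) are matched by tolerance. A helper accepts
  a critical value directly (`InclusionSpec.from_z`) for conventions stated
  that way, e.g. z = 2.493, the value whose confidence-interval-rule
  denominator is the golden ratio (p_incl ≈ 0.98733).
- `eta` (default 0.1): acceptable relative error around the true mean.
- `PowerSpec(alpha=0.05, beta=0.20)`: the z-sum z_{1−α/2}+z_{1−β} is computed
  (≈2.8016, multiplier 2·z_sum² ≈ 15.698). Published sample-size tables were
  produced with the two-decimal convention z_sum = 2.80 (multiplier 15.68);
  `PowerSpec(z_sum=2.80)` reproduces them, and tests that assert printed
  tables say so explicitly.
- Infinite trials or subjects are accepted as `math.inf` everywhere a limit
  makes sense and return the analytic limit (the σ²_t/n term vanishes).
- Rounding is never implicit: every formula returns the real value, and
  `round_count` applies `ceil` (default for reports — a count must guarantee
  the error bound), `nearest` (halves away from zero; some published counts
  use it), or `raw`. Before rounding, values are snapped to 9 decimals so
  counts that are integers up to floating-point dust (e.g.
  15.68·0.5/0.04 = 196.00000000000003) are not ceil'd one unit high.

## Synthetic-data generator

The Monte Carlo engine emulates amplitude data as lognormal — positive,
right-skewed, and moment-matched exactly: a target arithmetic mean m and SD s
give log-scale parameters log(m²/√(m²+s²)) and log(1+s²/m²). At s/m = 0.25,
0.5, 0.75, 1.0 the implied skewness is 0.77, 1.63, 2.67, 4.0. Correlated
subject-mean pairs use the exponential of a bivariate normal with log-scale
covariance log(1+r·σ²_s/(μ₁μ₂)). Hierarchy: subject means are lognormal
(μ_s, σ_s); each subject's trials are lognormal around that mean with common
SD σ_t in mV (so the per-subject CV varies across subjects — its population
mean is σ_t·E[1/m] = σ_t(1+CV²_s)/μ_s, not σ_t/μ_s).

Simulation protocols: error curves report, per trial count n, the 95th
percentile across replicate subjects (or replicate populations) of the
absolute error of the running mean divided by the true mean (division is by
the configured true mean, so non-unit means behave sensibly); t curves
average the mean and the c4-corrected SD of running paired differences across
replicate population pairs before forming t = mean/(sd/√N). The c4 factor is
the truncated series 1 − 1/(4N) − 7/(32N²) − 19/(128N³), within 5·10⁻³ of the
exact gamma-ratio form even at N = 2. Default replicate count is 10,000.

Randomness: one numpy `Generator` per simulation call, seeded from
`SeedSequence(seed, stream)` with a distinct stream per protocol; replicates
are rows of vectorized draws (chunked to bound memory). Runs are
bit-reproducible under a fixed seed within this implementation; across
implementations only statistical reproducibility is promised.

What the generator does *not* emulate: amplitude drift and serial
correlation within a session, attentional state changes, floor effects at
threshold intensities, and recording artifacts. Tests passing on this
generator therefore validate the formulas under ideal stationary skewed
data, not robustness to those real-world effects.

## Estimation choices

- Per-subject SD uses the n−1 denominator; skewness is the bias-corrected
  sample skewness (undefined below 3 trials or for constant data → NaN).
- Pooled within-subject SD is the square root of the trial-count-weighted
  mean of per-subject variances (reduces to the plain mean of variances for
  rectangular matrices).
- The asymptotic between-subject SD inverts the variance decomposition; if
  the observed variance does not exceed the noise term σ²_t/n the
  decomposition is degenerate — `asymptotic_sigma_subjects` raises, while
  `estimate_population` reports 0 with a warning flag so batch pipelines can
  proceed.
- The CV_trials population summary is the arithmetic mean of per-subject CVs
  with a min–max range. Note the estimator bias: on lognormal data at
  n = 100 the SD/mean ratio underestimates by ~3–4% (it vanishes as n
  grows); heavy-tailed data may warrant a normalizing transform before
  estimation, which this package deliberately does not automate.
- Split-half correlation correlates the mean of trials 1..b with the mean of
  trials b+1..2b across subjects, in recorded order. It is an attenuated
  (lower-bound) estimate of the asymptotic correlation — the attenuation
  formula with n = b predicts it. Outlier handling is diagnostic only: a
  leave-one-out correlation vector is returned, never an automatic
  exclusion, because no defensible automatic criterion exists at typical N.
- Disattenuated correlations can leave [−1, 1] on noisy inputs; they are
  returned unclipped with an `in_bounds` flag rather than silently truncated.
- The planning report's conservative construction takes μ₁ as the lower
  confidence limit of the estimated population mean, μ̂·(1−η̂(N,n)), and
  μ₂ = μ₁/2 — a deliberately pessimistic detectable difference for
  intensity-comparison designs.

## Test and validation scale

The analytic worked examples and sample-size grids are exact and instant.
Monte Carlo validation runs the full 10,000-replicate protocols (a few
seconds each, vectorized): single-subject curves agree with the closed form
within 5% relative for n ≥ 5 at CV ≤ 0.75 and within 8% at CV = 1.0 — the
small-n gap at high CV is a real central-limit-theorem effect of heavy skew
(about −5% at n = 5, persisting at 50,000 replicates), not Monte Carlo
noise — population curves within 5%, and t curves within 3% for n ≥ 10.
Generator fidelity is checked at 10⁶ draws (moments within 4 MC standard
errors; empirical skewness within 5%). Parameter recovery uses 20 seeds of
500-subject × 100-trial fixtures, comparing the across-seed mean to truth
within 3 SEM.

One published table entry is knowingly not reproduced: the population-error
table of the 20-subject session gives 17.7/18.2/19.3/16.9% at
n = 30/20/10/∞ from the rounded parameters (μ = 1.48, σ_s = 0.57,
σ_t = 1.01), but the n = 5 entry computes to 21.5%, not the printed 21.4% —
no parameter combination inside the rounding intervals of the printed inputs
matches all five entries at one decimal, so the corresponding test asserts
the printed value and fails, documenting the discrepancy rather than hiding
it.

## Known limitations

- Stationarity and i.i.d. trials are assumptions of convenience; long
  sessions violate them in ways the framework cannot see.
- The normal-approximation power formula is slightly anticonservative at
  very small N compared to exact noncentral-t power.
- CV estimates on heavily skewed data carry small-sample bias (above);
  planning from few trials per subject inherits it.
- The equal-variance paired model cannot represent designs where an
  intervention changes variability, only where it shifts the mean.
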