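# mepplan

Trial-count and sample-size planning for trial-averaged evoked-potential
experiments — the motivating case is TMS motor evoked potentials (MEPs),
whose single-trial peak-to-peak amplitude is notoriously variable, but the
formulas apply to any measure estimated by averaging repeated trials within
subjects (reaction times, other evoked responses, …).

It is written for experimenters planning such studies: instead of
rule-of-thumb trial counts ("use 30 trials"), it computes the error and power
consequences of any choice of trials *n* and subjects *N* from a handful of
variability parameters.

## The model

Single-trial amplitude within a subject has mean μ_trials and SD σ_trials
(CV_trials = σ_trials/μ_trials); subject means vary around the population
mean μ_subjects with asymptotic SD σ_subjects. Averaging n trials leaves a
noise term in the observed between-subject variance:

    σ²_subjects(n) = σ²_subjects + σ²_trials / n

Everything follows from that decomposition and a normal approximation for the
averages (z = z_{1−α/2}, the two-sided critical value of the inclusion
probability p_incl):

| question | formula |
|---|---|
| trials for a single-subject mean within ±η | n_opt = (z·CV_trials/η)² |
| error of a single-subject mean at n trials | η(n) = z·CV_trials/√n |
| error of a population mean at N subjects × n trials | η(N,n) = z·√(σ²_s + σ²_t/n)/(μ_s√N) |
| expected paired t (r = asymptotic correlation; r=0 ⇒ unpaired) | t = Δμ / √(2[σ²_s(1−r) + σ²_t/n]/N) |
| subjects for power 1−β at two-sided α | N_opt(n) = 2[σ²_s(1−r) + σ²_t/n]·(z_{1−α/2}+z_{1−β})²/Δμ² |
| test-retest correlation at n trials | r(n) = r·σ²_s/(σ²_s + σ²_t/n) |

A Monte Carlo engine (`mepplan.simulate`) validates each formula under
moment-matched lognormal amplitude distributions, and an estimation module
(`mepplan.estimate`) extracts all parameters from a recorded subjects×trials
amplitude matrix (tidy or wide CSV). Two older, n_max-bounded trial-count
definitions are included for comparison and labelled deprecated.

## Worked example

```
$ python examples/population_error_tradeoff.py
N=20 subjects, mu=1.0 mV, sigma_s=0.5 mV, sigma_t=0.5 mV
  n=  1 trials -> population-mean error +/-31.0%
  n=  5 trials -> population-mean error +/-24.0%
  n= 10 trials -> population-mean error +/-23.0%
  n= 30 trials -> population-mean error +/-22.3%
  n=100 trials -> population-mean error +/-22.0%
  n=inf trials -> population-mean error +/-21.9%
```

Reading: with 20 subjects the population-mean error can never drop below
±21.9% (the subject-sampling floor z·σ_s/(μ√N)) no matter how many trials are
recorded — going from 10 trials to infinitely many buys only one percentage
point. Trials matter for single-subject estimates; subjects matter for
population estimates and power. The other scripts in `examples/` walk through
single-subject planning, sample-size tables, reliability attenuation,
simulation validation, and the data-to-report workflow.

The same computations are available from a shell:

```
$ mepplan power --mu1 1.23 --mu2 0.62 --sigma-subjects 0.57 \
    --sigma-trials 1.01 --r 0.61 --z-sum 2.80 --n inf
{ ... "results": { "eq11_n_opt_raw": 5.3395..., "eq11_n_opt_rounded": 6.0 ... } }
```

i.e. six subjects suffice for that within-subject comparison at α=0.05,
power 0.80, given unlimited trials. Subcommands: `plan-single`,
`plan-population`, `power`, `reliability`, `simulate`, `estimate`,
`fixture`; every report echoes its parameters so results are reproducible
from the report alone.

## Layout

- `src/mepplan/planner.py` — single-subject trial-count equations
- `src/mepplan/population.py` — population error, power, reliability
- `src/mepplan/simulate.py` — lognormal Monte Carlo engine and fixtures
- `src/mepplan/estimate.py` — parameter estimation and planning reports
- `src/mepplan/io.py`, `src/mepplan/cli.py` — file formats and CLI
- `docs/methods.md` — model assumptions, numerical choices, limitations
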