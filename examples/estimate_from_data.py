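"""From a recorded session to a planning report.

Builds a synthetic 20-subject x 100-trial session (in place of real
recordings), estimates the planning parameters, and prints the report a
real dataset would produce via ``mepplan estimate``.
"""

import math

from mepplan import (
    SubjectPopulation,
    estimate_population,
    generate_fixture,
    planning_report,
    split_half_r,
)

pop = SubjectPopulation(mu_subjects=1.48, sigma_subjects=0.57, sigma_trials=1.01)
data = generate_fixture(pop, N=20, n=100, seed=42)

est = estimate_population(data)
print("estimated from the session:")
print(f"  mu_subjects              = {est.mu_subjects:.2f} mV")
print(f"  sigma_subjects (at n)    = {est.sigma_subjects_at_n:.2f} mV")
print(f"  sigma_subjects (asympt.) = {est.sigma_subjects_asymptotic:.2f} mV")
print(f"  sigma_trials (pooled)    = {est.sigma_trials_pooled:.2f} mV")
print(f"  CV_trials mean (range)   = {est.cv_trials_mean:.2f} "
      f"({est.cv_trials_range[0]:.2f}-{est.cv_trials_range[1]:.2f})")

sh = split_half_r(data, block=20)
print(f"  split-half r (block 20)  = {sh.r:.2f}  (lower bound on asymptotic r)")

report = planning_report(est, eta=0.1, p_incl=0.95)
single = report["single_subject"]
print(f"\nfor +/-10% single-subject error: {single['n_opt']:.0f} trials "
      f"(range {single['n_opt_range'][0]:.0f}-{single['n_opt_range'][1]:.0f})")
print("population-mean error at this N:")
for n, eta in zip(report["population_error"]["trials"], report["population_error"]["eta"]):
    label = "inf" if math.isinf(n) else f"{n:3.0f}"
    print(f"  n={label} -> +/-{eta:.1%}")
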