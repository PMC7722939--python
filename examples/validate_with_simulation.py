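"""Check the analytic error curve against lognormal Monte Carlo data.

Amplitudes are not normal, but the planning formulas only need the averages
to be: simulating skewed lognormal trials shows the closed-form curve and the
empirical 95th-percentile error agree to a few percent.
"""

import numpy as np

from mepplan import SimConfig, error_single, simulate_single_subject_curve

CV = 0.5
cfg = SimConfig(n_replicates=5_000, n_trials_max=100, seed=0)
curve = simulate_single_subject_curve(CV, cfg)

print(f"lognormal trials, CV_trials={CV}, {cfg.n_replicates} simulated subjects")
print("  n    analytic   simulated")
for n in (5, 10, 20, 50, 100):
    analytic = error_single(n, CV)
    simulated = curve.values[n - 1]
    print(f"  {n:3d}   {analytic:7.1%}   {simulated:7.1%}")

rel = np.abs(curve.values[4:] - [error_single(n, CV) for n in curve.n_trials[4:]])
rel /= [error_single(n, CV) for n in curve.n_trials[4:]]
print(f"max relative deviation for n >= 5: {rel.max():.1%}")
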