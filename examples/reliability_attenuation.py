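"""Test-retest reliability is capped by trial noise.

An observed correlation between two sessions with n trials each is the
asymptotic correlation shrunk by sigma_s^2 / (sigma_s^2 + sigma_t^2/n);
the classical disattenuation correction inverts the shrinkage.
"""

import math

from mepplan import disattenuate, reliability_at_n

R, SIGMA_S, SIGMA_T = 0.9, 0.5, 0.5

print(f"asymptotic r={R}, sigma_s={SIGMA_S} mV, sigma_t={SIGMA_T} mV")
for n in (1, 5, 10, 20, 100):
    r_n = reliability_at_n(R, SIGMA_S, SIGMA_T, n)
    print(f"  n={n:3d} trials -> observed r(n) = {r_n:.3f}")

# invert the attenuation: recover the asymptotic r from an observed one
n = 10
r_n = reliability_at_n(R, SIGMA_S, SIGMA_T, n)
obs_sd = math.sqrt(SIGMA_S**2 + SIGMA_T**2 / n)
corrected = disattenuate(r_n, obs_sd, SIGMA_T, n)
print(f"disattenuating r({n}) = {r_n:.3f} recovers r = {corrected.value:.3f} "
      f"(in bounds: {corrected.in_bounds})")
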