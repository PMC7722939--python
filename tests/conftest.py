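import numpy as np
import pytest

from mepplan import SubjectPopulation, generate_fixture

#: critical value z_{0.975} frozen from the inverse normal CDF
Z975 = 1.959963984540054


@pytest.fixture(scope="session")
def small_fixture():
    """A 20-subject x 100-trial synthetic matrix with Experiment-1-like spread."""
    pop = SubjectPopulation(mu_subjects=1.48, sigma_subjects=0.57, sigma_trials=1.01)
    return generate_fixture(pop, N=20, n=100, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
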