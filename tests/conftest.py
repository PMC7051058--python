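import numpy as np
import pytest

from icsgwis.simulate import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Small cohort with one strong causal interaction among five variants."""
    params = SimulationParams(betaI=-1.0, n_samples=400, n_variants=5,
                              n_causal=1, seed=42)
    return simulate_cohort(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
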