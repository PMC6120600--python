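import numpy as np
import pytest

from hemolag import CohortSpec, make_reference_signal, simulate_cohort

TR = 2.8
BAND = (0.01, 0.08)


@pytest.fixture(scope="session")
def ref128():
    """Band-limited 128-frame reference at TR 2.8 s."""
    return make_reference_signal(128, TR, BAND, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small noiseless cohort for exact ground-truth checks."""
    spec = CohortSpec(
        n_patients=4, n_behavioral=8, grid_dims=(12, 12, 12),
        noise_sd=0.0, seed=5,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default-noise cohort at desk scale for statistical checks."""
    spec = CohortSpec(n_patients=20, n_behavioral=30, grid_dims=(14, 14, 14), seed=7)
    return simulate_cohort(spec)
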