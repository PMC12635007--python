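import numpy as np
import pytest

from gamclock import CohortSimSpec, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def noiseless_cohort():
    """n=200 cohort, 3 genes, no measurement noise, decorrelated offsets."""
    spec = CohortSimSpec(
        n_subjects=200,
        age_range=(20.0, 100.0),
        genes=[("G1", 2.0, -0.010, 0.0),
               ("G2", 2.5, -0.012, 0.0),
               ("G3", 1.8, -0.008, 0.0)],
        offset_sd=10.0,
        seed=11,
    )
    return simulate_cohort(spec)
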