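import numpy as np
import pandas as pd
import pytest

from gipca.synthetic import (
    TrialSpec,
    default_cohort_spec,
    simulate_cohort,
    simulate_trial,
)


@pytest.fixture(scope="session")
def noiseless_trial():
    """One clean GI trial with distinct per-axis COP onsets."""
    return simulate_trial(TrialSpec(noise_sd=0.0, ml_onset_delay=0.05))


@pytest.fixture(scope="session")
def cohort_table() -> pd.DataFrame:
    """A 10+10 cohort at the full PD effect profile."""
    return simulate_cohort(default_cohort_spec(effect_scale=1.0, seed=42))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
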