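import numpy as np
import pandas as pd
import pytest

from lesionkinetics.data_io import CohortDataset
from lesionkinetics.synthetic import SyntheticConfig, generate


@pytest.fixture
def tiny_cohort() -> CohortDataset:
    """One patient, two lesions, hand-written diameters on the trial schedule."""
    rows = [
        ("P1", "L1", 0, 30.0), ("P1", "L1", 42, 22.0),
        ("P1", "L1", 84, 18.0), ("P1", "L1", 147, 21.0),
        ("P1", "L2", 0, 15.0), ("P1", "L2", 42, 11.0),
        ("P1", "L2", 84, 9.0), ("P1", "L2", 147, 12.0),
    ]
    df = pd.DataFrame(rows, columns=["patient_id", "lesion_id", "day", "diameter_mm"])
    return CohortDataset(df, (0, 42, 84, 147, 210), arm_label="tiny")


@pytest.fixture(scope="session")
def default_cohort():
    """A 200-patient arm generated from the default configuration."""
    cfg = SyntheticConfig(n_patients=200, seed=20240917)
    return generate(cfg)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Zero-variance, zero-noise cohort: every lesion on the population line."""
    cfg = SyntheticConfig(
        n_patients=15, seed=3, bsl_log_sd=0.0, decay_sd_between=0.0,
        decay_sd_within=0.0, regrowth_sd_between=0.0, regrowth_sd_within=0.0,
        residual_sd=0.0, dropout_at_pd=False)
    return generate(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
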