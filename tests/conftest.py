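import numpy as np
import pandas as pd
import pytest

from agegap.cohort import Cohort, SimulationConfig, generate_cohort


def make_cohort_frame(
    n_cu: int,
    n_ad: int,
    *,
    ages=None,
    carriers_cu: int = 0,
    females_cu: int = 0,
    seed: int = 0,
) -> Cohort:
    """Hand-built cohort with a single informative predictor (no noise)."""
    rng = np.random.default_rng(seed)
    n = n_cu + n_ad
    if ages is None:
        ages = rng.uniform(55, 90, size=n)
    ages = np.asarray(ages, dtype=float)
    diagnosis = ["CU"] * n_cu + ["AD"] * n_ad
    apoe4 = ["carrier"] * carriers_cu + ["noncarrier"] * (n - carriers_cu)
    gender = ["female"] * females_cu + ["male"] * (n - females_cu)
    frame = pd.DataFrame(
        {
            "subject_id": [f"S-{i:05d}" for i in range(n)],
            "age": ages,
            "diagnosis": diagnosis,
            "apoe4": apoe4,
            "gender": gender,
            "education": 15.0,
            "vol_001": 100.0 - ages,
        }
    )
    return Cohort(frame, ("vol_001",))


@pytest.fixture
def noise_free_config() -> SimulationConfig:
    """Small, fully deterministic generative setup: features exactly linear
    in latent brain age, constant injected AD gap of 8 years."""
    return SimulationConfig(
        n_cu=200,
        n_ad=100,
        n_volumetric=8,
        n_medical=2,
        gap_intercept=8.0,
        gap_slope=0.0,
        carrier_extra_gap=0.0,
        female_extra_gap=0.0,
        feature_noise_sd=0.0,
        seed=42,
    )


@pytest.fixture
def noise_free_cohort(noise_free_config):
    return generate_cohort(noise_free_config)
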