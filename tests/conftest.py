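import numpy as np
import pandas as pd
import pytest

from postop_recovery.cohort import GeneratorConfig, generate_cohort
from postop_recovery.features import FeatureConfig
from postop_recovery.reference import DropSpec, build_reference_profiles
from postop_recovery.streams import EPOCH, generate_streams


def fast_generator_config(**overrides) -> GeneratorConfig:
    """Coarse storage cadences so cohort-scale tests stay quick; all other
    conditions are the generator defaults."""
    base = dict(chest_hr_dt=32.0, chest_rr_dt=32.0, wrist_dt=30.0)
    base.update(overrides)
    return GeneratorConfig(**base)


def fast_feature_config(**overrides) -> FeatureConfig:
    base = dict(welch_fs=2.0)
    base.update(overrides)
    return FeatureConfig(**base)


def series_from_seconds(seconds, values, day: int = 0) -> pd.Series:
    """Build a timestamp-indexed stream from seconds-of-day offsets."""
    idx = EPOCH + pd.to_timedelta(np.asarray(seconds, dtype=float)
                                  + day * 86400.0, unit="s")
    return pd.Series(np.asarray(values, dtype=float), index=idx)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(fast_generator_config(n_patients=12, seed=42))


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    return build_reference_profiles(small_cohort, DropSpec(), horizon=21)


@pytest.fixture(scope="session")
def one_patient_streams(small_cohort, small_profiles):
    cfg = fast_generator_config(n_patients=12, seed=42)
    patient = small_cohort[0]
    return patient, generate_streams(patient, small_profiles[patient.patient_id], cfg), cfg
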