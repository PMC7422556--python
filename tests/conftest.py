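from __future__ import annotations

import numpy as np
import pytest

from shoehar.pipeline import PipelineConfig, run_calibration, run_synthetic_study
from shoehar.synthetic import SyntheticConfig, simulate_lab_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_lab_sessions():
    """Six synthetic calibration subjects, enough for LOSO behaviour tests."""
    cfg = SyntheticConfig(n_subjects=6, seed=11)
    return simulate_lab_study(cfg)


@pytest.fixture(scope="session")
def small_lab_features(small_lab_sessions):
    from shoehar.features import build_feature_set, concat_feature_sets

    return concat_feature_sets(
        [build_feature_set(rec, log, "lab") for rec, log in small_lab_sessions]
    )


@pytest.fixture(scope="session")
def default_study():
    """The full seeded default study (35 lab + 29 free-living subjects), RF.

    Session-scoped: this is the expensive end-to-end run the qualitative
    reproduction checks share.
    """
    cfg = PipelineConfig(families=("rf",), seed=1)
    cal, val = run_synthetic_study(cfg, n_lab=35, n_freeliving=29)
    return cal, val
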