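import numpy as np
import pytest

from sttkit import generate_cohort, generate_record
from sttkit.io import FEATURE_COLUMNS
from sttkit.pipeline import build_config, features_for_record


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_config():
    return build_config()


@pytest.fixture(scope="session")
def healthy_record():
    """Noise-free healthy record plus ground truth."""
    return generate_record("healthy", seed=11)


@pytest.fixture(scope="session")
def ischemic_record():
    return generate_record("ischemic", seed=11)


@pytest.fixture(scope="session")
def cohort_features(default_config):
    """Feature matrix of the frozen 30+30 synthetic cohort (seed 7).

    Computed once per session; shared by the model tests and the
    end-to-end acceptance criterion.
    """
    X, y = [], []
    for rec, _ in generate_cohort(30, 30, seed=7):
        fv = features_for_record(rec, default_config)
        assert fv.complete, f"{rec.record_id} flagged: {fv.flags}"
        X.append(fv.as_row())
        y.append(1 if rec.label == "ischemic" else 0)
    return np.array(X), np.array(y), list(FEATURE_COLUMNS)
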