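import numpy as np
import pytest

import ecgnoise as e

COHORT_SEED = 20260


@pytest.fixture(scope="session")
def small_cohort():
    """10-patient cohort at reduced size, shared across test modules."""
    spec = e.default_cohort_spec(seed=COHORT_SEED, blocks_per_patient=40)
    return e.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_blocks(small_cohort):
    return e.segment_cohort(small_cohort)


@pytest.fixture(scope="session")
def small_retained(small_blocks):
    return e.filter_patients(small_blocks)


@pytest.fixture(scope="session")
def small_dataset(small_blocks, small_retained):
    return e.build_dataset(small_blocks, small_retained)


@pytest.fixture(scope="session")
def trained_forest(small_dataset):
    """A forest + scaler fit on the whole small dataset (for tracking tests)."""
    from ecgnoise.models import ModelConfig, build_classifier

    scaler = e.fit_feature_scaler(small_dataset.X)
    model = build_classifier(ModelConfig("rforest", {"ntrees": 50, "nfeats": 4}, seed=1))
    model.fit(e.apply_feature_scaler(small_dataset.X, scaler), small_dataset.y)
    return model, scaler


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
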