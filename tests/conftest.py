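import numpy as np
import pytest

from phenoclust.preprocess import (extract_features, impute_cohort, screen_patients,
                                   standardize)
from phenoclust.synth import CohortConfig, generate_cohort

# cluster sizes proportional to the six-group reference configuration
REFERENCE_SIZES = np.array([68, 100, 46, 144, 290, 95], dtype=float)
REFERENCE_PROPS = tuple((REFERENCE_SIZES / REFERENCE_SIZES.sum()).tolist())


def separable_config(n_patients=400, seed=3, **overrides) -> CohortConfig:
    defaults = dict(
        n_patients=n_patients,
        n_clusters=6,
        cluster_proportions=REFERENCE_PROPS,
        n_lab_variables=12,
        n_static_continuous=4,
        n_static_binary=4,
        mean_measurements_per_variable=21,
        cluster_mean_shift=3.0,
        n_informative_features=10,
        seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def features_of(cohort):
    screened, _ = screen_patients(cohort)
    return standardize(extract_features(impute_cohort(screened)))


@pytest.fixture(scope="session")
def separable_cohort():
    return generate_cohort(separable_config())


@pytest.fixture(scope="session")
def separable_features(separable_cohort):
    return features_of(separable_cohort)


@pytest.fixture(scope="session")
def separable_truth(separable_cohort):
    return separable_cohort.true_clusters()


@pytest.fixture(scope="session")
def blob_data():
    """Three well-separated 2-D gaussian blobs with labels."""
    rng = np.random.default_rng(0)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    labels = np.repeat([0, 1, 2], 40)
    X = centers[labels] + rng.normal(scale=0.3, size=(120, 2))
    return X, labels
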