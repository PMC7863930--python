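import logging
import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mirdiag.cohort import CohortSpec, generate_cohort

logging.getLogger("mirdiag").setLevel(logging.ERROR)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="SCAD-SVM did not converge")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def small_cohort():
    """63/63 training, 25/81 validation, 120 features, 6 strong markers."""
    spec = CohortSpec(
        p=120,
        informative_ids=tuple(range(6)),
        effect_sizes=(2.0, 2.0, 2.0, -2.0, -2.0, -2.0),
        seed=1234,
    )
    expression, metadata, truth = generate_cohort(spec)
    return spec, expression, metadata, truth


def split_training(expression, metadata):
    mask = (metadata["cohort"] == "training").to_numpy()
    X = expression.iloc[:, mask.nonzero()[0]]
    y = (metadata.loc[mask, "label"] == "case").astype(int).to_numpy()
    return X, y


def split_validation(expression, metadata):
    mask = (metadata["cohort"] == "validation").to_numpy()
    X = expression.iloc[:, mask.nonzero()[0]]
    y = (metadata.loc[mask, "label"] == "case").astype(int).to_numpy()
    return X, y
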