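"""Shared fixtures.

The session-scoped fixtures below hold the standard simulation benchmark
(20,000 balanced training observations, 2,000 balanced test observations
under the wide log-uniform prior) and the predictors trained on it.  They
are expensive (minutes) and are only materialized when a test asks for
them; the unit-test files use small local data instead.
"""

import numpy as np
import pytest

from oudiverge import (
    PriorSpec,
    calibrate_cutoff,
    generate_dataset,
    train_nn,
    train_rf,
    train_svm,
    tune_svm,
)

# classification/regression hyperparameters selected by the full
# cross-validation grid search (two hidden layers, L1-only elastic net)
NN_CLF_CONFIG = dict(hidden_layers=2, lam=4.327e-4, gamma_mix=1.0)
NN_REG_CONFIG = dict(hidden_layers=2, lam=7.499e-5, gamma_mix=1.0)

TRAIN_SEED = 101
TEST_SEED = 202
FIT_SEED = 7


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def standard_train():
    return generate_dataset(PriorSpec(), 10_000, 10_000, TRAIN_SEED)


@pytest.fixture(scope="session")
def standard_test():
    return generate_dataset(PriorSpec(), 1_000, 1_000, TEST_SEED)


@pytest.fixture(scope="session")
def nn_classifier(standard_train):
    return train_nn(standard_train, "classify", random_state=FIT_SEED, **NN_CLF_CONFIG)


@pytest.fixture(scope="session")
def nn_regressor(standard_train):
    return train_nn(standard_train, "regress", random_state=FIT_SEED, **NN_REG_CONFIG)


@pytest.fixture(scope="session")
def rf_classifier(standard_train):
    return train_rf(standard_train, "classify", random_state=FIT_SEED)


@pytest.fixture(scope="session")
def svm_classifier(standard_train):
    gamma, C, _ = tune_svm(standard_train, "classify", random_state=FIT_SEED)
    return train_svm(standard_train, "classify", gamma=gamma, C=C, random_state=FIT_SEED)


@pytest.fixture(scope="session")
def distance_variants(standard_train):
    """All four calibrated distance classifiers keyed by (metric, representation)."""
    out = {}
    for metric in ("manhattan", "euclidean"):
        for representation in ("absolute", "relative"):
            c, cv_acc, model = calibrate_cutoff(
                standard_train, metric, representation, random_state=FIT_SEED
            )
            out[(metric, representation)] = model
    return out


@pytest.fixture(scope="session")
def distance_classifier(distance_variants):
    """The best-performing variant: Manhattan on absolute profiles."""
    return distance_variants[("manhattan", "absolute")]
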