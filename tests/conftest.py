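"""Shared fixtures.

The trained posterior estimator is expensive (a few minutes of CPU), so it
is built once per session and shared by the inference and acceptance tests.
Everything is seeded; the fixture is deterministic.
"""

import numpy as np
import pytest

from cnvrevert.inference import PriorSpec, build_training_set, train_npe
from cnvrevert.wf import PopulationConfig


@pytest.fixture(scope="session")
def two_locus_prior():
    return PriorSpec()


@pytest.fixture(scope="session")
def experiment_config():
    return PopulationConfig()


@pytest.fixture(scope="session")
def training_set(two_locus_prior, experiment_config):
    return build_training_set(
        two_locus_prior,
        experiment_config,
        n=2000,
        noise_sigma=0.02,
        rng=np.random.default_rng(1),
    )


@pytest.fixture(scope="session")
def trained_estimator(training_set):
    return train_npe(training_set, seed=0)
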