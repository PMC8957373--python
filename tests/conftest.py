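"""Shared fixtures: synthetic cohorts at two scales.

The desk-scale cohort (20 subjects, 100 cubes per provocation, default
noise) is the calibrated study-condition dataset; it and its LOSO run
are session-scoped because several evaluation tests share them.  The
mini cohort is a smaller, cheaper dataset for harness plumbing tests.
"""

import numpy as np
import pytest

from oxymosaic.evaluation import loso_run
from oxymosaic.synthetic import Profile, simulate_cohort
from oxymosaic.weighting import compute_weight_vector

DESK_SEED = 1
LOSO_SEED = 0


@pytest.fixture(scope="session")
def desk_cohort():
    return simulate_cohort(n_subjects=20, seed=DESK_SEED)


@pytest.fixture(scope="session")
def desk_weights(desk_cohort):
    return compute_weight_vector(desk_cohort.spectra.y)


@pytest.fixture(scope="session")
def desk_loso(desk_cohort, desk_weights):
    return loso_run(desk_cohort.spectra, weight_vector=desk_weights,
                    n_hidden=3, seed=LOSO_SEED)


@pytest.fixture(scope="session")
def mini_cohort():
    return simulate_cohort(
        n_subjects=4, seed=7, profile=Profile(frame_shape=(64, 64), n_cubes=30))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
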