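import numpy as np
import pytest

import sdmrisk as s


@pytest.fixture(scope="session")
def small_spec():
    return s.LandscapeSpec(n_rows=30, n_cols=40, n_layers=12, seed=7,
                           mask_fraction=0.1)


@pytest.fixture(scope="session")
def small_stack(small_spec):
    return s.generate_env_stack(small_spec)


@pytest.fixture(scope="session")
def truth_and_suitability(small_stack):
    truth = s.default_truth_model(small_stack)
    return truth, s.truth_suitability(small_stack, truth)


@pytest.fixture(scope="session")
def occurrence_sample(truth_and_suitability):
    _, suit = truth_and_suitability
    return s.sample_occurrences(suit, n_presence=60, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
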