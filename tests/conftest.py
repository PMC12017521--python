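import numpy as np
import pytest

from archstiff.pipeline import analyze_trial
from archstiff.synthetic import SyntheticGaitConfig, generate_trial


@pytest.fixture(scope="session")
def clean_case():
    """Default noise-free synthetic trial, its ground truth, and analysis."""
    trial, truth = generate_trial(SyntheticGaitConfig())
    return trial, truth, analyze_trial(trial)


@pytest.fixture(scope="session")
def clean_trial(clean_case):
    return clean_case[0]


@pytest.fixture(scope="session")
def clean_truth(clean_case):
    return clean_case[1]


@pytest.fixture(scope="session")
def clean_result(clean_case):
    return clean_case[2]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
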