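import numpy as np
import pytest

from reqrank import datasets
from reqrank.survey_io import Indicator, ResponseRecord, ResponseTable


@pytest.fixture(scope="session")
def indicators():
    return datasets.load_indicators()


@pytest.fixture()
def small_responses():
    """Two respondents × two indicators, hand-written."""
    return ResponseTable(
        [
            ResponseRecord("r1", "older_adult", "A1", "must_be", "dislike"),
            ResponseRecord("r1", "older_adult", "A2", "like", "dislike"),
            ResponseRecord("r2", "caregiver", "A1", "neutral", "dislike"),
            ResponseRecord("r2", "caregiver", "A2", "neutral", "neutral"),
        ]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
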