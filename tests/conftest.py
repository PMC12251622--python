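import numpy as np
import pytest

from pulsebp.features import default_registry
from pulsebp.preprocess import PeakDetectorConfig, preprocess_record
from pulsebp.synth import SynthConfig, generate_record

FS = 62.4725


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def clean_record():
    """A clean 30 s synthetic record at a fixed 75 bpm."""
    cfg = SynthConfig(duration_s=30.0, hr_range_bpm=(75.0, 75.0), seed=11)
    return generate_record(cfg, 0)


@pytest.fixture(scope="session")
def roi_pairs(clean_record):
    """(segment, shaped ROI) pairs from the clean record."""
    _, pairs = preprocess_record(clean_record, PeakDetectorConfig())
    assert pairs, "preprocessing the clean record must yield ROIs"
    return pairs


@pytest.fixture(scope="session")
def sample_roi(roi_pairs):
    return roi_pairs[2][1]


@pytest.fixture(scope="session")
def sample_segment(roi_pairs):
    return roi_pairs[2][0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
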