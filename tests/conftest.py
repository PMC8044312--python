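import numpy as np
import pytest

from twac import BeatModelParams, delineate_record, detect_r_peaks, build_twac, synthesize_record


@pytest.fixture(scope="session")
def beat_params():
    return BeatModelParams()


@pytest.fixture(scope="session")
def clean_synth(beat_params):
    """Noise-free 15 s default record with exact ground truth."""
    return synthesize_record(beat_params, 15.0, 1000.0, 0, noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_delineated(clean_synth):
    """(synthetic record, detected annotations) on the clean record."""
    det = delineate_record(clean_synth.record, clean_synth.annotations.r_peaks)
    return clean_synth, det


@pytest.fixture(scope="session")
def clean_series(clean_delineated):
    synth, det = clean_delineated
    return build_twac(synth.record, det)
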