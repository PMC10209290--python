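import numpy as np
import pytest

import wavebeat as wb


@pytest.fixture(scope="session")
def ecg_record():
    """60 s synthetic ECG at 250 Hz, 70 BPM, study-condition noise."""
    return wb.synth_ecg(wb.default_ecg_config(seed=11))


@pytest.fixture(scope="session")
def ppg_record():
    """60 s synthetic PPG at 250 Hz, 70 BPM, study-condition noise."""
    return wb.synth_ppg(wb.default_ppg_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
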