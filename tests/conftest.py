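import numpy as np
import pytest

from pulsebp.synthetic import SubjectProfile, synth_paired
from pulsebp.wavelet_core import SignalStream


@pytest.fixture(scope="session")
def paired_clean():
    """A 20 s noiseless paired recording at 75 bpm with exact truth."""
    prof = SubjectProfile(
        hr_mean=75.0, hr_jitter=0.0, pat=0.25, noise_snr=None, seed=11
    )
    return synth_paired(prof, 20.0)


@pytest.fixture(scope="session")
def paired_80s_clean():
    """An 80 s noiseless paired recording (one full analysis segment)."""
    prof = SubjectProfile(
        hr_mean=75.0, hr_jitter=0.02, pat=0.25, noise_snr=None, seed=21
    )
    return synth_paired(prof, 80.0)


@pytest.fixture()
def flat_stream():
    return SignalStream(np.zeros(30_000), 1200.0, kind="ecg")
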