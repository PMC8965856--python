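import numpy as np
import pytest

from qeeg.recording import CleanEpoch, EegRecording
from qeeg.simulate import EegSimParams

#: Midline-only generator parameters used by the simulation-heavy tests;
#: channels are statistically independent, so restricting synthesis to the
#: three analyzed electrodes changes nothing but run time.
MIDLINE_SIM = dict(channels=("Fz", "Cz", "Pz"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def midline_params():
    return EegSimParams(**MIDLINE_SIM)


def make_epoch(data, fs=200.0, labels=None, duration=None,
               session="rest_eyes_closed"):
    """Wrap a channels x samples array as a CleanEpoch."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    labels = tuple(labels) if labels else tuple(f"Ch{i}" for i in range(data.shape[0]))
    rec = EegRecording("fixture", session, fs, labels, data)
    return CleanEpoch(rec, duration=duration or data.shape[1] / fs)
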