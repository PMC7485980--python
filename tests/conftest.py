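import numpy as np
import pytest

from lumapulse.timeseries import EpochResponse


def make_response(post_values, fs=50.0, polarity="dark", epoch=1,
                  pre_s=0.5):
    """EpochResponse with zero pre-stimulus baseline and given post values."""
    n_pre = int(round(pre_s * fs))
    # pre samples cover [-pre_s, 0]; post sample j sits at (j + 1) / fs
    times = np.arange(-n_pre, len(post_values) + 1) / fs
    values = np.concatenate([np.zeros(n_pre + 1),
                             np.asarray(post_values, float)])
    return EpochResponse(epoch=epoch, polarity=polarity, times_s=times,
                         values=values, n_flashes=6, frame_rate_hz=fs)


@pytest.fixture
def response_factory():
    return make_response
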