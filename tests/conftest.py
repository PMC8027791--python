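import numpy as np
import pytest

from assrpipe.preprocessing import Epochs


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def sinusoid_epochs(
    freq=40.0,
    amplitude=1.0,
    phases=(0.0,),
    fs=500.0,
    window=(-0.5, 1.0),
    stim=(0.0, 0.5),
    channel_labels=("Fz",),
    condition="assr40",
):
    """Epochs holding a pure sinusoid burst with given per-trial phases."""
    n = int(round((window[1] - window[0]) * fs))
    t = window[0] + np.arange(n) / fs
    mask = (t >= stim[0]) & (t < stim[1])
    data = np.zeros((len(phases), len(channel_labels), n))
    for i, phi in enumerate(phases):
        x = np.zeros(n)
        x[mask] = amplitude * np.cos(2 * np.pi * freq * t[mask] + phi)
        data[i] = x
    return Epochs(
        data=data,
        tmin=window[0],
        fs=fs,
        condition=condition,
        channel_labels=list(channel_labels),
    )
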