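import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

import ictal2d as it


@pytest.fixture(scope="session")
def bonn_like_record():
    """A single-channel ictal record in the ASCII-clip shape
    (173.61 Hz, 23.6 s)."""
    spec = it.SyntheticSpec(
        n_subjects=1, records_per_subject=1, channels=1,
        fs=173.61, duration_s=23.6, ictal_band=(8.0, 12.0),
        ictal_amplitude_ratio=4.0, seed=11,
    )
    return it.generate_synthetic(spec, "ictal")


@pytest.fixture(scope="session")
def multichannel_slice():
    """One 2 s slice of a 23-channel 256 Hz ictal record."""
    spec = it.SyntheticSpec(
        n_subjects=1, records_per_subject=1, channels=23,
        fs=256.0, duration_s=10.0, seed=7,
    )
    rec = it.generate_synthetic(spec, "ictal")
    return it.slice_record(rec, it.WindowConfig(window_s=2.0))[0]


@pytest.fixture(scope="session")
def tiny_net():
    return it.build_network(it.tiny_spec(), seed=0)


def sinusoid_slice(freq_hz, fs=256.0, duration_s=2.0, n_channels=1,
                   amplitude=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    x = amplitude * np.sin(2 * np.pi * freq_hz * t)
    data = np.tile(x, (n_channels, 1))
    return it.Slice(data=data, fs=fs, t_start_s=0.0, label="nonseizure",
                    source=("S00", "r0"))
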