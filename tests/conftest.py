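import numpy as np
import pytest

from nvfuse.containers import Montage, MontageEntry, TimeSeriesRecording
from nvfuse.synth import SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_montage():
    """4 EEG + 1 EOG + 4 fNIRS covering the four PFC ROIs."""
    rois = ["L-dlPFC", "L-FP", "R-FP", "R-dlPFC"]
    entries = [
        MontageEntry(f"E{i}", "eeg", float(i), 60.0, 20.0, rois[i]) for i in range(4)
    ]
    entries.append(MontageEntry("VEOG", "eog", 30.0, 75.0, -10.0, "other"))
    entries += [
        MontageEntry(f"CH{i + 1}", "fnirs_od", float(i), 60.0, 15.0, rois[i])
        for i in range(4)
    ]
    return Montage(entries=entries)


@pytest.fixture
def eeg_recording(rng):
    """30 s of 4-channel broadband noise at 256 Hz, ~20 uV RMS."""
    data = rng.standard_normal((4, 30 * 256)) * 20.0
    return TimeSeriesRecording(
        data=data, fs=256.0, channel_labels=["E0", "E1", "E2", "E3"], modality="eeg"
    )


@pytest.fixture
def test_sim_params():
    """Reduced-scale simulation preset used throughout the suite."""
    return SimParams(n_eeg=8, n_fnirs=6, duration_s=150.0, noise_mix=0.5)


def make_sine_recording(freq, fs, dur_s, n_channels=1, amp=1.0):
    t = np.arange(int(dur_s * fs)) / fs
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (n_channels, 1))
    return TimeSeriesRecording(
        data=data, fs=float(fs),
        channel_labels=[f"S{i}" for i in range(n_channels)], modality="eeg",
    )
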