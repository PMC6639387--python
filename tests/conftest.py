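import numpy as np
import pytest

from eegslow import CohortSimParams, EEGSimParams, simulate_cohort, simulate_eeg
from eegslow.recording import EEGRecording, PowerSpectrum


@pytest.fixture(scope="session")
def clean_recording():
    """Artifact-free 60 s recording with a 9.5 Hz dominant rhythm."""
    return simulate_eeg(EEGSimParams(duration_s=60.0, peak_freq=9.5, seed=11))


@pytest.fixture(scope="session")
def cohort_500():
    """Stats-level synthetic cohort (no raw EEG) shared across tests."""
    table, _ = simulate_cohort(CohortSimParams(n_subjects=500, seed=42), eeg=False)
    table["stage"] = table["mmse_total"].map(
        __import__("eegslow").assign_stage
    )
    return table


def tone_recording(freq, amp=1.0, duration_s=300.0, fs=250.0):
    """Pure sinusoid on both channels: analytic band power amp^2/2."""
    t = np.arange(int(duration_s * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    return EEGRecording(data=np.vstack([x, x]), fs=fs)


def spectrum_from_bins(freqs, power):
    """Hand-built one-channel spectrum for oracle tests."""
    freqs = np.asarray(freqs, dtype=float)
    return PowerSpectrum(freqs=freqs, power=np.asarray(power, float)[None, :],
                         resolution=float(freqs[1] - freqs[0]))
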