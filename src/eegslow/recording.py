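"""Core in-memory containers for two-channel prefrontal EEG.

The study design this package serves records eyes-closed resting EEG from the
two prefrontal sites Fp1 and Fp2 (International 10/20 system) at 250 Hz for
five minutes, in microvolts. Everything downstream (filtering, artifact
screening, spectral biomarkers) operates on :class:`EEGRecording`;
:class:`PowerSpectrum` holds the one-sided periodogram per channel; and
:class:`BiomarkerSet` holds the three slowing biomarkers per channel and
channel-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

CHANNEL_NAMES = ("Fp1", "Fp2")


@dataclass
class EEGRecording:
    """Two-channel voltage time series with sampling metadata.

    Parameters
    ----------
    data : ndarray, shape (2, n_samples)
        Voltages in microvolts; row 0 is Fp1, row 1 is Fp2.
    fs : float
        Sampling rate in Hz.
    subject_id : str
        Identifier carried through the pipeline.
    events : list of dict
        Log of injected or detected artifact events (type, start_s,
        duration_s, amplitude_uV). Empty for clean recordings.
    """

    data: np.ndarray
    fs: float
    subject_id: str = "anonymous"
    events: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != 2:
            raise ValueError("data must have shape (2, n_samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy(), events=list(self.events))

    def slice(self, start_sample: int, n_samples: int) -> "EEGRecording":
        if start_sample < 0 or start_sample + n_samples > self.n_samples:
            raise ValueError("slice out of range")
        return EEGRecording(
            data=self.data[:, start_sample : start_sample + n_samples].copy(),
            fs=self.fs,
            subject_id=self.subject_id,
            events=list(self.events),
        )


@dataclass
class PowerSpectrum:
    """One-sided power spectrum per channel.

    ``power[c, k]`` is the spectral power (uV^2) of channel ``c`` in the bin
    centred at ``freqs[k]``; summing over bins recovers the mean square of the
    mean-removed signal (Parseval). ``resolution`` is the bin spacing fs/N.
    """

    freqs: np.ndarray
    power: np.ndarray
    resolution: float

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.power.shape[-1] != self.freqs.shape[0]:
            raise ValueError("power/freqs length mismatch")
        if np.any(self.power < -1e-12):
            raise ValueError("power must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.power.shape[0]


@dataclass
class ScreenResult:
    """Voltage-threshold artifact screen outcome for one recording.

    ``fraction`` maps channel name -> fraction of samples with |v| above the
    threshold; the screen fails iff that fraction strictly exceeds
    ``max_fraction`` on any channel.
    """

    threshold_uV: float
    max_fraction: float
    fraction: dict
    passed: bool


@dataclass
class BiomarkerSet:
    """Median frequency, peak frequency and alpha-to-theta ratio.

    ``mdf``/``pf``/``atr`` are the channel-averaged biomarker values
    (arithmetic mean of the per-channel biomarkers, not of the spectra);
    ``per_channel`` maps channel name -> dict of the three values.
    ``screens`` holds :class:`ScreenResult` at the reporting thresholds.
    """

    mdf: float
    pf: float
    atr: float
    per_channel: dict
    screens: dict = field(default_factory=dict)
    subject_id: str = "anonymous"
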