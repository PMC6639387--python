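"""Device filtering, artifact screening and spectral slowing biomarkers.

The measurement chain emulated here is a two-channel prefrontal EEG amplifier
whose front end applies three causal digital IIR Butterworth filters
(band-stop 55-65 Hz 2nd order, high-pass 2.6 Hz 1st order, low-pass 43 Hz 8th
order). Spectra are single full-length rectangular-window periodograms of the
mean-removed signal, and the three slowing biomarkers are computed within the
dominant 4-13 Hz band:

* MDF (median frequency): the first frequency bin, ascending, at which the
  cumulative 4-13 Hz power strictly exceeds half the in-band total.
* PF (peak frequency): the in-band argmax, ties broken to the lowest
  frequency.
* ATR (alpha-to-theta ratio): the linear power ratio of the alpha band
  [8, 13) Hz to the theta band [4, 8) Hz, equivalently exp of the difference
  of the natural-log band powers.

Band edges use half-open bins [lo, hi) so theta and alpha partition 4-13 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from .recording import CHANNEL_NAMES, BiomarkerSet, EEGRecording, PowerSpectrum, ScreenResult

#: dominant oscillation band searched for MDF/PF (Hz, half-open)
DOMINANT_BAND = (4.0, 13.0)
#: theta band (Hz, half-open)
THETA_BAND = (4.0, 8.0)
#: alpha band (Hz, half-open)
ALPHA_BAND = (8.0, 13.0)

#: voltage screens reported per recording (uV)
SCREEN_THRESHOLDS_UV = (200.0, 150.0, 100.0)


def design_device_filters(fs: float) -> list[np.ndarray]:
    """Second-order sections of the amplifier's three Butterworth filters.

    Band-stop 2nd order with edges 55 and 65 Hz, high-pass 1st order at
    2.6 Hz, low-pass 8th order at 43 Hz. Requires fs > 130 Hz so the stop
    band sits below Nyquist.
    """
    if fs <= 130.0:
        raise ValueError(f"fs={fs} too low: 55-65 Hz stop band needs fs > 130 Hz")
    sos_stop = sps.butter(2, [55.0, 65.0], btype="bandstop", fs=fs, output="sos")
    sos_high = sps.butter(1, 2.6, btype="highpass", fs=fs, output="sos")
    sos_low = sps.butter(8, 43.0, btype="lowpass", fs=fs, output="sos")
    return [sos_stop, sos_high, sos_low]


def apply_device_filters(rec: EEGRecording, zero_phase: bool = False) -> EEGRecording:
    """Apply the amplifier filter cascade to each channel.

    Filters run causally (forward only) by default, matching an acquisition
    device; ``zero_phase=True`` switches to forward-backward filtering.
    """
    sos_list = design_device_filters(rec.fs)
    out = rec.copy()
    filt = sps.sosfiltfilt if zero_phase else sps.sosfilt
    for sos in sos_list:
        out.data = filt(sos, out.data, axis=-1)
    if zero_phase:
        out.data = np.ascontiguousarray(out.data)
    return out


def screen_artifacts(
    rec: EEGRecording, threshold_uV: float = 200.0, max_fraction: float = 0.10
) -> ScreenResult:
    """Fraction of samples exceeding a voltage threshold, per channel.

    The screen fails iff the fraction strictly exceeds ``max_fraction`` on
    any channel; at the default 200 uV / 10% this is the conventional
    serious-artifact exclusion rule. Screening is report-only: callers decide
    whether to act on a failure.
    """
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    if threshold_uV <= 0:
        raise ValueError("threshold must be positive")
    if not 0 < max_fraction <= 1:
        raise ValueError("max_fraction must be in (0, 1]")
    frac = {
        name: float(np.mean(np.abs(rec.data[i]) > threshold_uV))
        for i, name in enumerate(CHANNEL_NAMES)
    }
    passed = all(f <= max_fraction for f in frac.values())
    return ScreenResult(threshold_uV, max_fraction, frac, passed)


@dataclass
class CleanSlice:
    """Result of searching for an artifact-free contiguous window."""

    found: bool
    start_s: Optional[float] = None
    recording: Optional[EEGRecording] = None


def select_clean_slice(
    rec: EEGRecording, slice_s: float = 60.0, bound_uV: float = 80.0
) -> CleanSlice:
    """Earliest window of ``slice_s`` seconds with both channels in +/-bound.

    Scans sample-by-sample start positions and returns the first window in
    which every sample of both channels lies within +/-``bound_uV``. Returns
    a ``CleanSlice`` with ``found=False`` when no window qualifies.
    """
    win = int(round(slice_s * rec.fs))
    if win > rec.n_samples:
        raise ValueError("recording shorter than requested slice")
    bad = np.any(np.abs(rec.data) > bound_uV, axis=0)
    bad_idx = np.flatnonzero(bad)
    if bad_idx.size == 0:
        return CleanSlice(True, 0.0, rec.slice(0, win))
    # candidate starts: 0 and one past each bad sample; window must end
    # before the next bad sample
    boundaries = np.concatenate([bad_idx, [rec.n_samples]])
    starts = np.concatenate([[0], bad_idx + 1])
    for s in starts:
        nxt = boundaries[np.searchsorted(boundaries, s)]
        if nxt - s >= win:
            return CleanSlice(True, s / rec.fs, rec.slice(int(s), win))
    return CleanSlice(False)


def compute_periodogram(rec: EEGRecording) -> PowerSpectrum:
    """Single full-length rectangular-window periodogram per channel.

    The channel mean is removed, no segmentation or tapering is applied, and
    the one-sided scaling is such that the bin powers sum to the mean square
    of the mean-removed signal (Parseval). Resolution is fs/N.
    """
    if rec.n_samples < rec.fs:
        raise ValueError("need at least one second of data")
    if not np.all(np.isfinite(rec.data)):
        raise ValueError("non-finite samples in recording")
    freqs, power = sps.periodogram(
        rec.data,
        fs=rec.fs,
        window="boxcar",
        detrend="constant",
        scaling="spectrum",
        axis=-1,
    )
    return PowerSpectrum(freqs=freqs, power=power, resolution=rec.fs / rec.n_samples)


def _band_mask(ps: PowerSpectrum, lo: float, hi: float) -> np.ndarray:
    return (ps.freqs >= lo) & (ps.freqs < hi)


def band_power(
    ps: PowerSpectrum, lo_Hz: float, hi_Hz: float, channel: int = 0
) -> tuple[float, float]:
    """Summed band power and its natural log for one channel.

    Bins are half-open: lo <= f < hi. Returns ``(linear_sum, log_power)``;
    a zero band sum yields ``log_power = -inf`` rather than an error so the
    degenerate case stays representable.
    """
    if not (0 <= lo_Hz < hi_Hz <= ps.freqs[-1] + ps.resolution):
        raise ValueError("invalid band edges")
    mask = _band_mask(ps, lo_Hz, hi_Hz)
    if not mask.any():
        raise ValueError(f"no frequency bins in [{lo_Hz}, {hi_Hz}) Hz")
    lin = float(ps.power[channel, mask].sum())
    log = float(np.log(lin)) if lin > 0 else float("-inf")
    return lin, log


def median_frequency(ps: PowerSpectrum, channel: int = 0, band=DOMINANT_BAND) -> float:
    """MDF: first bin where cumulative 4-13 Hz power strictly exceeds half.

    Two steps: sum the in-band spectral power and halve it; then walk the
    band in ascending frequency and return the first bin at which the
    cumulative power strictly exceeds that half-total.
    """
    mask = _band_mask(ps, *band)
    p = ps.power[channel, mask]
    f = ps.freqs[mask]
    if p.size < 2:
        raise ValueError("fewer than two bins in the 4-13 Hz band")
    total = p.sum()
    if total <= 0:
        raise ValueError("zero in-band power")
    idx = int(np.argmax(np.cumsum(p) > total / 2.0))
    return float(f[idx])


def peak_frequency(ps: PowerSpectrum, channel: int = 0, band=DOMINANT_BAND) -> float:
    """PF: in-band (4-13 Hz) argmax frequency; ties break to the lowest."""
    mask = _band_mask(ps, *band)
    p = ps.power[channel, mask]
    f = ps.freqs[mask]
    if p.size < 2:
        raise ValueError("fewer than two bins in the 4-13 Hz band")
    if p.sum() <= 0:
        raise ValueError("zero in-band power")
    return float(f[int(np.argmax(p))])  # np.argmax returns the first maximum


def alpha_theta_ratio(
    ps: PowerSpectrum, channel: int = 0, alpha_band=ALPHA_BAND, theta_band=THETA_BAND
) -> float:
    """ATR: linear alpha-band [8,13) to theta-band [4,8) power ratio.

    Band powers are the natural-log-scale quantities exponentiated back,
    i.e. ATR = exp(ln P_alpha - ln P_theta) = P_alpha / P_theta.
    """
    pa, _ = band_power(ps, *alpha_band, channel=channel)
    pt, _ = band_power(ps, *theta_band, channel=channel)
    if pt <= 0:
        raise ValueError("zero theta power")
    return float(pa / pt)


def extract_biomarkers(rec: EEGRecording) -> BiomarkerSet:
    """Per-channel MDF/PF/ATR plus their arithmetic means across channels.

    Channel averaging is of the biomarker values, not of the spectra. The
    voltage screens at 200/150/100 uV are attached for reporting; no data are
    rejected here regardless of screen outcome.
    """
    ps = compute_periodogram(rec)
    per_channel = {}
    for i, name in enumerate(CHANNEL_NAMES):
        per_channel[name] = {
            "mdf": median_frequency(ps, channel=i),
            "pf": peak_frequency(ps, channel=i),
            "atr": alpha_theta_ratio(ps, channel=i),
        }
    screens = {
        int(th): screen_artifacts(rec, threshold_uV=th) for th in SCREEN_THRESHOLDS_UV
    }
    mean_of = lambda k: float(np.mean([per_channel[c][k] for c in CHANNEL_NAMES]))
    return BiomarkerSet(
        mdf=mean_of("mdf"),
        pf=mean_of("pf"),
        atr=mean_of("atr"),
        per_channel=per_channel,
        screens=screens,
        subject_id=rec.subject_id,
    )
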