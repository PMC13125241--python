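"""Preprocessing and spectral estimation.

Implements the preprocessing chain used for intracranial recordings in this
package: zero-phase low-pass at 150 Hz with line-noise notches at 60 and
120 Hz, bipolar re-referencing of adjacent contacts, event-locked epoching,
Morlet time-frequency decomposition over 80 log-spaced frequencies
(1-150 Hz, 2-30 cycles), log-transformed power z-scored against an
inter-trial-interval baseline with theta (3-8 Hz) and sub-band HFA
(70-150 Hz in 20-Hz sub-bands) reductions, and a zero-phase FIR theta
band-pass for lag analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from mne.time_frequency import tfr_array_morlet
from scipy import signal as sps

from .synth import LFPDataset

__all__ = [
    "Epochs",
    "TFR",
    "BandPower",
    "preprocess",
    "bipolar_reference",
    "epoch",
    "morlet_tfr",
    "band_power",
    "bandpass_theta",
    "resample_epochs",
    "default_freqs",
    "THETA_BAND",
    "HFA_SUBBANDS",
]

THETA_BAND = (3.0, 8.0)
HFA_SUBBANDS = tuple((lo, lo + 20.0) for lo in range(70, 131, 10))


def default_freqs(n: int = 80) -> tuple[np.ndarray, np.ndarray]:
    """80 log-spaced frequencies 1-150 Hz with matched 2-30 log-spaced cycles."""
    freqs = np.logspace(np.log10(1.0), np.log10(150.0), n)
    cycles = np.logspace(np.log10(2.0), np.log10(30.0), n)
    return freqs, cycles


def band_freqs(fmin: float, fmax: float) -> tuple[np.ndarray, np.ndarray]:
    """Subset of the standard wavelet bank within [fmin, fmax], keeping the
    matched cycle counts.  Short epochs that cannot carry the 1-Hz wavelet
    use a band-restricted bank."""
    freqs, cycles = default_freqs()
    sel = (freqs >= fmin) & (freqs <= fmax)
    if not sel.any():
        raise ValueError("empty frequency selection")
    return freqs[sel], cycles[sel]


@dataclass
class Epochs:
    """Event-locked epochs: channels x trials x samples, time 0 at lock."""

    data: np.ndarray
    fs: float
    times_ms: np.ndarray
    lock_event: str
    window_ms: tuple[float, float]
    valid: np.ndarray  # per-trial boolean mask

    def __post_init__(self) -> None:
        if not (self.window_ms[0] <= 0.0 <= self.window_ms[1]):
            raise ValueError("epoch window must cover the lock event")
        if len(self.valid) != self.data.shape[1]:
            raise ValueError("validity mask length must equal trial count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]


@dataclass
class TFR:
    """Morlet wavelet power: channels x trials x freqs x times."""

    power: np.ndarray
    freqs: np.ndarray
    cycles: np.ndarray
    times_ms: np.ndarray
    fs: float
    edge_valid: np.ndarray  # freqs x times mask, False within wavelet support of an edge

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


@dataclass
class BandPower:
    """Log-transformed, baseline-z-scored band power: channels x trials x times."""

    values: np.ndarray
    band: str
    times_ms: np.ndarray
    fs: float
    baseline_mean: np.ndarray  # per channel x frequency
    baseline_sd: np.ndarray


def preprocess(data: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase low-pass at 150 Hz and notch filters at 60 and 120 Hz.

    ``data`` may be any array whose last axis is time.  Output length equals
    input length (forward-backward filtering).
    """
    if fs <= 300.0:
        raise ValueError("sampling rate must exceed 300 Hz for the 150 Hz low-pass")
    nyq = fs / 2.0
    sos = sps.butter(4, 150.0 / nyq, "lowpass", output="sos")
    out = sps.sosfiltfilt(sos, data, axis=-1)
    for f0 in (60.0, 120.0):
        b, a = sps.iirnotch(f0, Q=30.0, fs=fs)
        out = sps.filtfilt(b, a, out, axis=-1)
    return out


def bipolar_reference(
    data: np.ndarray, adjacency: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Re-reference by subtracting adjacent contacts.

    ``adjacency`` lists (anode, cathode) channel indices; each output
    channel is ``data[anode] - data[cathode]``, cancelling signal common to
    the pair.  For n contacts on one shaft pass the n-1 neighbouring pairs.
    """
    n_ch = data.shape[0]
    out = []
    for a, c in adjacency:
        if not (0 <= a < n_ch and 0 <= c < n_ch):
            raise ValueError(f"contact pair ({a}, {c}) out of range")
        out.append(data[a] - data[c])
    return np.stack(out, axis=0)


_EVENT_ALIASES = {"trial_onset": "iti_end"}


def epoch(
    dataset: LFPDataset,
    lock_event: str,
    window_ms: tuple[float, float],
    channels: Optional[Sequence[int]] = None,
) -> Epochs:
    """Extract event-locked epochs from a trial-structured dataset.

    Trials lacking the lock event, or whose window exceeds the recorded
    segment, are masked invalid (zero-filled).
    """
    key = _EVENT_ALIASES.get(lock_event, lock_event)
    fs = dataset.fs
    i0 = int(round(window_ms[0] / 1000.0 * fs))
    i1 = int(round(window_ms[1] / 1000.0 * fs))
    n_out = i1 - i0
    ch_idx = np.arange(dataset.n_channels) if channels is None else np.asarray(channels)
    data = np.zeros((len(ch_idx), dataset.n_trials, n_out))
    valid = np.zeros(dataset.n_trials, dtype=bool)
    for t, ev in enumerate(dataset.events):
        t_event = ev.get(key)
        if t_event is None:
            continue
        center = int(round(t_event / 1000.0 * fs))
        lo, hi = center + i0, center + i1
        if lo < 0 or hi > dataset.n_samples:
            continue
        data[:, t, :] = dataset.signal[ch_idx, t, lo:hi]
        valid[t] = True
    times = (np.arange(i0, i1) / fs) * 1000.0
    return Epochs(
        data=data,
        fs=fs,
        times_ms=times,
        lock_event=lock_event,
        window_ms=tuple(window_ms),
        valid=valid,
    )


def resample_epochs(epochs: Epochs, fs_new: float) -> Epochs:
    """Polyphase resampling of epochs to a new rate (e.g. 100 Hz for
    connectivity, or to reconcile the 512 / 2000 Hz acquisition dialects)."""
    from fractions import Fraction

    frac = Fraction(fs_new / epochs.fs).limit_denominator(10000)
    data = sps.resample_poly(epochs.data, frac.numerator, frac.denominator, axis=-1)
    n_out = data.shape[-1]
    times = epochs.times_ms[0] + np.arange(n_out) / fs_new * 1000.0
    return Epochs(
        data=data,
        fs=fs_new,
        times_ms=times,
        lock_event=epochs.lock_event,
        window_ms=epochs.window_ms,
        valid=epochs.valid.copy(),
    )


def morlet_tfr(
    epochs: Epochs,
    freqs: Optional[np.ndarray] = None,
    cycles: Optional[np.ndarray] = None,
    decim: int = 1,
    output: str = "power",
) -> TFR:
    """Morlet wavelet time-frequency decomposition of epochs.

    Defaults to the 80-frequency, 2-30-cycle log-spaced bank.  Samples
    within half a wavelet support of either epoch edge are flagged invalid
    in ``edge_valid`` so statistics windows can exclude them.
    """
    if freqs is None or cycles is None:
        freqs, cycles = default_freqs()
    freqs = np.asarray(freqs, float)
    cycles = np.asarray(cycles, float)
    n_times = epochs.data.shape[-1]
    longest = cycles[0] / freqs[0] * epochs.fs
    if n_times < longest:
        raise ValueError(
            f"epoch ({n_times} samples) shorter than the widest wavelet "
            f"({longest:.0f} samples at {freqs[0]:.2f} Hz)"
        )
    # mne expects (n_epochs, n_channels, n_times)
    x = np.transpose(epochs.data, (1, 0, 2))
    out = tfr_array_morlet(
        x, epochs.fs, freqs, n_cycles=cycles, output=output, decim=decim, zero_mean=True
    )
    out = np.transpose(out, (1, 0, 2, 3))  # channels x trials x freqs x times
    times = epochs.times_ms[::decim][: out.shape[-1]]
    fs_out = epochs.fs / decim
    half_support = cycles / freqs / 2.0 * 1000.0  # ms
    t0, t1 = epochs.times_ms[0], epochs.times_ms[-1]
    edge_valid = (times[None, :] >= t0 + half_support[:, None]) & (
        times[None, :] <= t1 - half_support[:, None]
    )
    return TFR(
        power=out,
        freqs=freqs,
        cycles=cycles,
        times_ms=np.asarray(times),
        fs=fs_out,
        edge_valid=edge_valid,
    )


def _band_average(logz: np.ndarray, freqs: np.ndarray, band: str) -> np.ndarray:
    if band == "theta":
        sel = (freqs >= THETA_BAND[0]) & (freqs <= THETA_BAND[1])
        if not sel.any():
            raise ValueError("no frequencies within the theta band")
        return logz[:, :, sel, :].mean(axis=2)
    if band == "hfa":
        subs = []
        for lo, hi in HFA_SUBBANDS:
            sel = (freqs >= lo) & (freqs <= hi)
            if sel.any():
                subs.append(logz[:, :, sel, :].mean(axis=2))
        if not subs:
            raise ValueError("no frequencies within the HFA range")
        return np.mean(subs, axis=0)
    raise ValueError(f"unknown band {band!r}")


def band_power(
    tfr: TFR,
    band: str,
    baseline_tfr: TFR,
    baseline_window_ms: Optional[tuple[float, float]] = None,
    fs_out: float = 20.0,
) -> BandPower:
    """Log-transform, z-score per frequency against an ITI baseline, reduce
    to a band, and downsample.

    The baseline TFR (which may be ``tfr`` itself restricted to an ITI time
    window via ``baseline_window_ms``) is pooled across its trials and
    timepoints per channel and frequency; timepoints inside a wavelet's
    edge-contaminated zone are excluded from the pool.  Theta averages the
    3-8 Hz frequencies directly; HFA first averages within the 20-Hz
    sub-bands 70-90 ... 130-150 Hz, then across sub-bands, limiting the 1/f
    bias of a single wide band.  Output is block-averaged down to ``fs_out``
    (default 20 Hz).
    """
    if not np.array_equal(tfr.freqs, baseline_tfr.freqs):
        raise ValueError("baseline TFR must share the frequency grid")
    eps = np.finfo(float).tiny
    base_log = np.log(baseline_tfr.power + eps)
    tmask = np.ones(baseline_tfr.times_ms.size, dtype=bool)
    if baseline_window_ms is not None:
        lo, hi = baseline_window_ms
        tmask = (baseline_tfr.times_ms >= lo) & (baseline_tfr.times_ms <= hi)
    n_ch, n_tr, n_f, _ = base_log.shape
    mu = np.empty((n_ch, n_f))
    sd = np.empty((n_ch, n_f))
    for fi in range(n_f):
        sel = tmask & baseline_tfr.edge_valid[fi]
        if sel.sum() < 2:
            raise ValueError(
                f"baseline window has <2 edge-clean samples at "
                f"{baseline_tfr.freqs[fi]:.2f} Hz"
            )
        block = base_log[:, :, fi, :][:, :, sel]
        mu[:, fi] = block.mean(axis=(1, 2))
        sd[:, fi] = block.std(axis=(1, 2))
    if np.any(sd <= 0):
        raise ValueError("zero-variance baseline for at least one frequency")
    logz = (np.log(tfr.power + eps) - mu[:, None, :, None]) / sd[:, None, :, None]
    vals = _band_average(logz, tfr.freqs, band)
    block = max(int(round(tfr.fs / fs_out)), 1)
    n_blocks = vals.shape[-1] // block
    vals = vals[..., : n_blocks * block].reshape(*vals.shape[:-1], n_blocks, block)
    vals = vals.mean(axis=-1)
    times = tfr.times_ms[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    return BandPower(
        values=vals,
        band=band,
        times_ms=times,
        fs=tfr.fs / block,
        baseline_mean=mu,
        baseline_sd=sd,
    )


def bandpass_theta(
    data: np.ndarray, fs: float, band: tuple[float, float] = THETA_BAND
) -> np.ndarray:
    """Zero-phase FIR band-pass (Hamming window) in the theta band.

    Applied forward-backward so the group delay is zero; the amplitude
    envelope is then obtainable via the analytic signal
    (``scipy.signal.hilbert``).
    """
    if fs < 100.0:
        raise ValueError("sampling rate too low for the theta band-pass")
    nyq = fs / 2.0
    numtaps = int(3.3 * fs / 2.0)
    numtaps += 1 - numtaps % 2  # odd
    n_times = data.shape[-1]
    max_taps = max((n_times - 2) // 3, 3)
    if numtaps > max_taps:
        numtaps = max_taps + (1 - max_taps % 2)
    taps = sps.firwin(numtaps, band, pass_zero=False, window="hamming", fs=fs)
    return sps.filtfilt(taps, [1.0], data, axis=-1, padlen=min(3 * numtaps, n_times - 1))
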