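"""Across-trial theta-band connectivity with trial-shuffle significance.

Connectivity is computed over time but across trials: at every timepoint
the per-trial Morlet cross-spectra (3-8 Hz) between two channels are
combined into one of three volume-conduction-robust metrics —

* ``imag_coh`` — absolute imaginary part of coherency,
* ``ppc`` — pairwise phase consistency (bias-free phase concentration),
* ``wpli_debiased`` — debiased squared weighted phase-lag index,

plus ``coh`` (magnitude coherence), which is sensitive to zero-lag mixing
and exists as a contrast metric.  Significance comes from shuffling the
trial labels of one member of the pair, comparing each timepoint against
its null one-sidedly (elevated direction), FDR-correcting across
timepoints (Benjamini-Hochberg), and requiring a contiguous run of
significant timepoints of at least 100 ms.  Trial-level coupling is
summarised separately by amplitude-envelope correlation, which is stable
at single-trial resolution where coherence is not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from statsmodels.stats.multitest import multipletests

from .spectral import Epochs, default_freqs, THETA_BAND
from mne.time_frequency import tfr_array_morlet

__all__ = [
    "CoherenceSeries",
    "SignificantPair",
    "EnvelopeSynchrony",
    "theta_spectra",
    "metric_from_spectra",
    "coherence_over_trials",
    "permutation_test",
    "envelope_synchrony",
    "METRICS",
]

METRICS = ("imag_coh", "ppc", "wpli_debiased", "coh")

FS_CONN = 100.0


@dataclass
class CoherenceSeries:
    pair: tuple[str, str]
    metric: str
    values: np.ndarray  # per-timepoint, band-averaged over 3-8 Hz
    times_ms: np.ndarray
    fs: float
    valid: np.ndarray  # timepoint mask clear of wavelet edge effects


@dataclass
class SignificantPair:
    series: CoherenceSeries
    p_values: np.ndarray  # FDR-corrected, 1.0 outside the valid mask
    sig_mask: np.ndarray
    significant: bool
    longest_run_ms: float
    n_perm: int


@dataclass
class EnvelopeSynchrony:
    pair: tuple[str, str]
    r: np.ndarray  # per-trial Pearson correlation
    fisher_z: np.ndarray
    z_scored: np.ndarray  # Fisher-z standardized within pair across trials
    dropped: np.ndarray  # trials dropped (constant envelope)


def theta_band_freqs() -> tuple[np.ndarray, np.ndarray]:
    """Theta subset of the standard 80-frequency wavelet bank."""
    freqs, cycles = default_freqs()
    sel = (freqs >= THETA_BAND[0]) & (freqs <= THETA_BAND[1])
    return freqs[sel], cycles[sel]


def theta_spectra(
    epochs: Epochs, channels: Optional[list[int]] = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complex Morlet coefficients in the theta band for selected channels.

    Returns ``(W, times_ms, valid)`` with ``W`` of shape
    (channels, trials, freqs, times).  ``valid`` masks timepoints within
    half a wavelet support of the epoch edges.
    """
    freqs, cycles = theta_band_freqs()
    data = epochs.data if channels is None else epochs.data[channels]
    x = np.transpose(data, (1, 0, 2))
    W = tfr_array_morlet(
        x, epochs.fs, freqs, n_cycles=cycles, output="complex", zero_mean=True
    )
    W = np.transpose(W, (1, 0, 2, 3))
    half_ms = cycles / freqs / 2.0 * 1000.0
    t0, t1 = epochs.times_ms[0], epochs.times_ms[-1]
    valid = np.all(
        (epochs.times_ms[None, :] >= t0 + half_ms[:, None])
        & (epochs.times_ms[None, :] <= t1 - half_ms[:, None]),
        axis=0,
    )
    return W, epochs.times_ms.copy(), valid


def metric_from_spectra(Wa: np.ndarray, Wb: np.ndarray, metric: str) -> np.ndarray:
    """Across-trial connectivity metric, band-averaged over frequencies.

    ``Wa``/``Wb`` are (..., trials, freqs, times) complex wavelet
    coefficients of the two channels on an identical trial set; leading axes
    broadcast (used to batch permutations).  The metric is computed per
    (frequency, timepoint) across the trial axis, then averaged over
    frequencies.
    """
    if Wa.shape[-3:] != Wb.shape[-3:]:
        raise ValueError("trial/frequency/time axes of the pair must match")
    n = Wa.shape[-3]
    ax = -3
    X = Wa * np.conj(Wb)  # per-trial cross-spectrum
    if metric in ("imag_coh", "coh"):
        Sxy = X.mean(axis=ax)
        Sxx = (np.abs(Wa) ** 2).mean(axis=ax)
        Syy = (np.abs(Wb) ** 2).mean(axis=ax)
        C = Sxy / np.sqrt(Sxx * Syy + np.finfo(float).tiny)
        vals = np.abs(C.imag) if metric == "imag_coh" else np.abs(C)
    elif metric == "ppc":
        phases = X / (np.abs(X) + np.finfo(float).tiny)
        R = np.abs(phases.sum(axis=ax))
        vals = (R**2 - n) / (n * (n - 1))
    elif metric == "wpli_debiased":
        im = X.imag
        sum_im = im.sum(axis=ax)
        sum_sq = (im**2).sum(axis=ax)
        sum_abs = np.abs(im).sum(axis=ax)
        denom = sum_abs**2 - sum_sq
        vals = np.where(
            denom > 0, (sum_im**2 - sum_sq) / np.where(denom > 0, denom, 1.0), 0.0
        )
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    return vals.mean(axis=-2)  # band average over frequencies


def coherence_over_trials(
    epochs: Epochs,
    chan_a: int,
    chan_b: int,
    metric: str = "imag_coh",
    labels: Optional[tuple[str, str]] = None,
    min_trials: int = 20,
) -> CoherenceSeries:
    """Per-timepoint theta connectivity between two channels of one Epochs.

    Requires at least ``min_trials`` valid trials for estimator stability.
    """
    keep = epochs.valid
    if keep.sum() < min_trials:
        raise ValueError(f"need >= {min_trials} valid trials, got {int(keep.sum())}")
    W, times, valid = theta_spectra(epochs, channels=[chan_a, chan_b])
    vals = metric_from_spectra(W[0][keep], W[1][keep], metric)
    pair = labels or (f"ch{chan_a}", f"ch{chan_b}")
    return CoherenceSeries(
        pair=pair, metric=metric, values=vals, times_ms=times, fs=epochs.fs, valid=valid
    )


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for m in mask:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def permutation_test(
    epochs: Epochs,
    chan_a: int,
    chan_b: int,
    metric: str = "imag_coh",
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    min_ms: float = 100.0,
    contiguous: bool = True,
    labels: Optional[tuple[str, str]] = None,
) -> SignificantPair:
    """Trial-shuffle significance of a connectivity series.

    The trial labels of the second channel are shuffled ``n_perm`` times;
    each timepoint's observed value is compared one-sidedly (elevated) to
    its null, p-values are FDR-corrected across timepoints, and the pair is
    flagged significant when a run of corrected-significant timepoints
    spans at least ``min_ms``.  With ``contiguous=False`` the rule counts
    total (not necessarily contiguous) significant time.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    keep = epochs.valid
    W, times, valid = theta_spectra(epochs, channels=[chan_a, chan_b])
    Wa, Wb = W[0][keep], W[1][keep]
    observed = metric_from_spectra(Wa, Wb, metric)
    n_trials = Wa.shape[0]
    null = np.empty((n_perm, observed.size))
    for k in range(n_perm):
        null[k] = metric_from_spectra(Wa, Wb[rng.permutation(n_trials)], metric)

    idx = np.flatnonzero(valid)
    p_raw = (1.0 + (null[:, idx] >= observed[idx]).sum(axis=0)) / (n_perm + 1.0)
    p_corr = np.ones_like(observed)
    if idx.size:
        p_corr[idx] = multipletests(p_raw, alpha=alpha, method="fdr_bh")[1]
    sig = p_corr < alpha
    min_samples = np.inf if np.isinf(min_ms) else int(np.ceil(min_ms / 1000.0 * epochs.fs))
    if contiguous:
        run = _longest_run(sig)
    else:
        run = int(sig.sum())
    significant = bool(np.isfinite(min_samples) and run >= min_samples)
    series = CoherenceSeries(
        pair=labels or (f"ch{chan_a}", f"ch{chan_b}"),
        metric=metric,
        values=observed,
        times_ms=times,
        fs=epochs.fs,
        valid=valid,
    )
    return SignificantPair(
        series=series,
        p_values=p_corr,
        sig_mask=sig,
        significant=significant,
        longest_run_ms=run / epochs.fs * 1000.0,
        n_perm=n_perm,
    )


def envelope_synchrony(
    env_a: np.ndarray,
    env_b: np.ndarray,
    times_ms: np.ndarray,
    windows_ms: np.ndarray,
    labels: tuple[str, str] = ("a", "b"),
    min_window_ms: float = 500.0,
) -> EnvelopeSynchrony:
    """Trial-level Pearson correlation of two amplitude envelopes.

    ``env_a``/``env_b`` are (trials, times) band-power envelopes (theta or
    HFA), ``windows_ms`` an array of per-trial (start, end) approach windows
    on the ``times_ms`` axis — the window should exclude the pre-movement
    period.  Correlations are Fisher-z transformed and standardized within
    the pair across trials.  Trials with a constant envelope (undefined r)
    are dropped.
    """
    if env_a.shape != env_b.shape:
        raise ValueError("envelope arrays must share shape")
    n_trials = env_a.shape[0]
    windows_ms = np.asarray(windows_ms, float)
    r = np.full(n_trials, np.nan)
    dropped = np.zeros(n_trials, dtype=bool)
    for t in range(n_trials):
        lo, hi = windows_ms[t]
        if hi - lo < min_window_ms:
            raise ValueError(f"approach window of trial {t} shorter than {min_window_ms} ms")
        sel = (times_ms >= lo) & (times_ms <= hi)
        a, b = env_a[t, sel], env_b[t, sel]
        if a.std() == 0 or b.std() == 0:
            dropped[t] = True
            continue
        r[t] = np.corrcoef(a, b)[0, 1]
    ok = ~dropped
    z = np.full(n_trials, np.nan)
    z[ok] = np.arctanh(np.clip(r[ok], -0.999999, 0.999999))
    zs = np.full(n_trials, np.nan)
    if ok.sum() > 1 and np.nanstd(z[ok]) > 0:
        zs[ok] = (z[ok] - z[ok].mean()) / z[ok].std()
    return EnvelopeSynchrony(
        pair=labels, r=r, fisher_z=z, z_scored=zs, dropped=dropped
    )
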