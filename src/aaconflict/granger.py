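"""Directed theta-band connectivity: net time-reversed spectral Granger
causality and cross-correlation lag analysis.

Directionality between two channels is scored two independent ways:

1. **Net spectral Granger causality.**  At every timepoint a bivariate
   VAR(12) is fit by OLS across trials on a short sliding window of the
   100-Hz signals; the fitted coefficients and innovation covariance give
   the parametric spectral decomposition from which frequency-resolved
   Granger scores are read off and averaged over 3-8 Hz.  Because rising or
   falling SNR alone can fake directionality, the same score computed on
   time-reversed epochs is subtracted:

       net(a, b) = [GC(a->b) - GC(b->a)] - [GC_rev(a->b) - GC_rev(b->a)]

   which is antisymmetric under swapping the pair (positive = a leads b).
   Significance comes from shuffling trial labels of one channel, a
   two-sided test on |net| per timepoint, FDR across timepoints, and a
   500-ms (50 timepoints at 100 Hz) duration rule.

2. **Cross-correlation lag.**  The theta band-passed approach windows of
   all trials are concatenated into one sequence per channel and the CCF
   over +/-25 lags (+/-250 ms at 100 Hz) is computed; the best lag is
   retained if the peak correlation beats the top 5% of a null built by
   shuffling trial order while keeping trial lengths constant, so the
   concatenation discontinuities are matched in every surrogate.

The two methods agree on a region pair only when both give P+ > 0.95 for
the same sign; that consensus rule is what downstream inference interprets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .spectral import Epochs

__all__ = [
    "GCConfig",
    "NetGrangerSeries",
    "CrossCorrResult",
    "DirectionalPair",
    "spectral_gc",
    "net_granger",
    "gc_permutation_test",
    "concat_approach",
    "cross_correlation_test",
    "direction_consensus",
]


@dataclass(frozen=True)
class GCConfig:
    """Parameters of the Granger stage.

    ``n_lags=12`` acts as a spectral smoothing parameter; the per-timepoint
    fit uses a centered ``window_samples`` sliding window (310 ms at
    100 Hz), pooled across trials so each OLS sees well over 8 x n_lags
    rows.  Only the final ``analysis_ms`` of the epoch are scored, to avoid
    edge artifacts.
    """

    n_lags: int = 12
    band: tuple[float, float] = (3.0, 8.0)
    fs: float = 100.0
    epoch_ms: tuple[float, float] = (-2500.0, 0.0)
    analysis_ms: tuple[float, float] = (-1500.0, 0.0)
    window_samples: int = 31
    n_freqs: int = 6
    n_perm: int = 1000
    alpha: float = 0.05
    duration_ms: float = 500.0
    literal_eq: bool = False

    def __post_init__(self) -> None:
        if self.n_lags < 1:
            raise ValueError("n_lags must be >= 1")
        if self.duration_ms > (self.analysis_ms[1] - self.analysis_ms[0]):
            pass  # allowed: then nothing can ever qualify

    @property
    def freq_grid(self) -> np.ndarray:
        return np.linspace(self.band[0], self.band[1], self.n_freqs)

    @property
    def duration_samples(self) -> float:
        if np.isinf(self.duration_ms):
            return np.inf
        return int(np.ceil(self.duration_ms / 1000.0 * self.fs))


@dataclass
class NetGrangerSeries:
    pair: tuple[str, str]
    net: np.ndarray  # per-timepoint band-averaged net score; positive = a leads b
    times_ms: np.ndarray
    fs: float
    p_corrected: Optional[np.ndarray] = None
    sig_mask: Optional[np.ndarray] = None
    qualifies: Optional[bool] = None
    n_sig: Optional[int] = None


@dataclass
class CrossCorrResult:
    pair: tuple[str, str]
    lags: np.ndarray  # samples; positive = channel a leads
    corr: np.ndarray
    best_lag: int
    best_lag_ms: float
    max_corr: float
    p_value: float
    retained: bool
    n_perm: int


@dataclass
class DirectionalPair:
    region_pair: tuple[str, str]
    p_pos_granger: Optional[float]
    p_pos_ccf: Optional[float]
    threshold: float = 0.95
    consensus: Optional[bool] = None
    direction: Optional[int] = None  # +1: first region leads; -1: second leads

    def __post_init__(self) -> None:
        pg, pc = self.p_pos_granger, self.p_pos_ccf
        if pg is None or pc is None:
            self.consensus = None
            return
        hi, lo = self.threshold, 1.0 - self.threshold
        if pg > hi and pc > hi:
            self.consensus, self.direction = True, +1
        elif pg < lo and pc < lo:
            self.consensus, self.direction = True, -1
        else:
            self.consensus = False


# ---------------------------------------------------------------------------
# VAR machinery.  For a pair (A, B) we accumulate, per timepoint, cumulative
# cross-products of the 2 targets and 2*p lagged regressors across trials;
# sliding-window sums of these products are the OLS normal equations of every
# window at once, so the per-timepoint VAR fits (and all their trial-label
# permutations, which only alter the A-x-B product blocks) are batched.


def _series_stack(x: np.ndarray, p: int) -> np.ndarray:
    """(trials, T) -> (p+1, trials, T): the series and its lags 1..p."""
    out = np.zeros((p + 1,) + x.shape)
    out[0] = x
    for k in range(1, p + 1):
        out[k, :, k:] = x[:, :-k]
    return out


def _window_sums(G: np.ndarray, centers: np.ndarray, half: int) -> np.ndarray:
    """Sliding-window sums of (u, v, T) products over [c-half, c+half]."""
    csum = np.concatenate(
        [np.zeros(G.shape[:2] + (1,)), np.cumsum(G, axis=-1)], axis=-1
    )
    return csum[..., centers + half + 1] - csum[..., centers - half]


def _gc_from_products(
    M: np.ndarray, n_rows: int, p: int, freqs: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Both-direction spectral GC from windowed normal-equation products.

    ``M`` is (..., 2+2p, 2+2p) with row/col order [A, B, A lags 1..p,
    B lags 1..p].  Returns band-resolved GC arrays ``(gc_ab, gc_ba)`` of
    shape (..., n_freqs): gc_ab is the influence A -> B.
    """
    XtX = M[..., 2:, 2:]
    XtY = M[..., 2:, :2]
    YtY = M[..., :2, :2]
    # Ridge-less OLS; tiny jitter guards against exact singularity.
    eye = np.eye(XtX.shape[-1])
    coef = np.linalg.solve(XtX + 1e-10 * eye, XtY)  # (..., 2p, 2)
    resid = YtY - np.swapaxes(XtY, -1, -2) @ coef
    dof = max(n_rows - 2 * p, 1)
    Sigma = resid / dof  # innovation covariance (..., 2, 2)

    # VAR coefficient matrices A_k: A_k[i, j] = effect of series j at lag k
    # on series i.  coef rows: [A lags 1..p, B lags 1..p]; columns: target.
    lead = coef.shape[:-2]
    Ak = np.empty(lead + (p, 2, 2))
    Ak[..., :, 0, 0] = coef[..., 0:p, 0]
    Ak[..., :, 0, 1] = coef[..., p : 2 * p, 0]
    Ak[..., :, 1, 0] = coef[..., 0:p, 1]
    Ak[..., :, 1, 1] = coef[..., p : 2 * p, 1]

    omega = 2.0 * np.pi * freqs / fs  # (F,)
    phases = np.exp(-1j * np.outer(omega, np.arange(1, p + 1)))  # (F, p)
    # E(f) = I - sum_k A_k e^{-i w k}, shape (..., F, 2, 2)
    Af = np.tensordot(phases, np.moveaxis(Ak, -3, 0), axes=(1, 0))  # (F, ..., 2, 2)
    Af = np.moveaxis(Af, 0, -3)
    E = np.eye(2) - Af
    # 2x2 inverse, batched
    det = E[..., 0, 0] * E[..., 1, 1] - E[..., 0, 1] * E[..., 1, 0]
    H = np.empty_like(E)
    H[..., 0, 0] = E[..., 1, 1]
    H[..., 1, 1] = E[..., 0, 0]
    H[..., 0, 1] = -E[..., 0, 1]
    H[..., 1, 0] = -E[..., 1, 0]
    H = H / det[..., None, None]

    s_xx = Sigma[..., 0, 0][..., None]
    s_yy = Sigma[..., 1, 1][..., None]
    s_xy = Sigma[..., 0, 1][..., None]
    Hxx, Hxy = H[..., 0, 0], H[..., 0, 1]
    Hyx, Hyy = H[..., 1, 0], H[..., 1, 1]
    # Spectral densities of each channel (real parts of S = H Sigma H*).
    Sxx = (
        s_xx * np.abs(Hxx) ** 2
        + s_yy * np.abs(Hxy) ** 2
        + 2.0 * s_xy * (Hxx * np.conj(Hxy)).real
    )
    Syy = (
        s_xx * np.abs(Hyx) ** 2
        + s_yy * np.abs(Hyy) ** 2
        + 2.0 * s_xy * (Hyx * np.conj(Hyy)).real
    )
    eps = np.finfo(float).tiny
    # Geweke: GC(B->A, f) = ln Sxx / (Sxx - (s_yy - s_xy^2/s_xx) |Hxy|^2)
    part_y = (s_yy - s_xy**2 / np.maximum(s_xx, eps)) * np.abs(Hxy) ** 2
    part_x = (s_xx - s_xy**2 / np.maximum(s_yy, eps)) * np.abs(Hyx) ** 2
    gc_ba = np.log(np.maximum(Sxx, eps) / np.maximum(Sxx - part_y, eps))
    gc_ab = np.log(np.maximum(Syy, eps) / np.maximum(Syy - part_x, eps))
    return np.maximum(gc_ab, 0.0), np.maximum(gc_ba, 0.0)


def _net_gc(
    A: np.ndarray,
    B: np.ndarray,
    config: GCConfig,
    centers: np.ndarray,
    perms: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Net time-reversed GC at the given window centers.

    ``perms`` is an optional (n_perm, n_trials) array of trial-label
    permutations applied to channel B; the identity is always row 0 of the
    output.  Returns (1 + n_perm, n_centers).
    """
    p = config.n_lags
    half = (config.window_samples - 1) // 2
    n_trials, T = A.shape
    freqs = config.freq_grid
    n_rows = n_trials * config.window_samples

    perm_list = [np.arange(n_trials)]
    if perms is not None:
        perm_list += [np.asarray(q) for q in perms]

    out = np.empty((len(perm_list), centers.size))
    Za_f = _series_stack(A, p)  # (p+1, trials, T)
    Zb_f = _series_stack(B, p)
    Za_r = _series_stack(A[:, ::-1], p)
    Zb_r = _series_stack(B[:, ::-1], p)
    centers_r = (T - 1) - centers

    def blocks(Za, Zb, perm, cts):
        # Product tensor in order [A0, B0, A lags, B lags]
        Zbp = Zb[:, perm, :]
        Gaa = np.einsum("uit,vit->uvt", Za, Za)
        Gbb = np.einsum("uit,vit->uvt", Zb, Zb)  # invariant to perm
        Gab = np.einsum("uit,vit->uvt", Za, Zbp)
        na = p + 1
        G = np.empty((2 * na, 2 * na, T))
        # index map: 0 -> A0, 1 -> B0, 2..p+1 -> A lags, p+2.. -> B lags
        a_idx = np.r_[0, np.arange(2, p + 2)]
        b_idx = np.r_[1, np.arange(p + 2, 2 * p + 2)]
        G[np.ix_(a_idx, a_idx)] = Gaa
        G[np.ix_(b_idx, b_idx)] = Gbb
        G[np.ix_(a_idx, b_idx)] = Gab
        G[np.ix_(b_idx, a_idx)] = np.swapaxes(Gab, 0, 1)
        M = _window_sums(G, cts, half)  # (2+2p, 2+2p, n_centers)
        return np.moveaxis(M, -1, 0)  # (n_centers, 2+2p, 2+2p)

    for k, perm in enumerate(perm_list):
        Mf = blocks(Za_f, Zb_f, perm, centers)
        Mr = blocks(Za_r, Zb_r, perm, centers_r)
        gc_ab_f, gc_ba_f = _gc_from_products(Mf, n_rows, p, freqs, config.fs)
        gc_ab_r, gc_ba_r = _gc_from_products(Mr, n_rows, p, freqs, config.fs)
        fwd = gc_ab_f.mean(axis=-1) - gc_ba_f.mean(axis=-1)
        rev_ab = gc_ab_r.mean(axis=-1)
        rev_ba = gc_ba_r.mean(axis=-1)
        if config.literal_eq:
            out[k] = fwd - rev_ab - rev_ba
        else:
            out[k] = fwd - (rev_ab - rev_ba)
    return out


def _analysis_centers(epochs: Epochs, config: GCConfig) -> np.ndarray:
    """Sample indices of scoreable timepoints within the analysis window."""
    p, half = config.n_lags, (config.window_samples - 1) // 2
    T = epochs.data.shape[-1]
    lo_ok = p + half
    hi_ok = T - 1 - p - half  # mirrored window must also fit lag context
    t = epochs.times_ms
    in_window = (t >= config.analysis_ms[0]) & (t <= config.analysis_ms[1])
    idx = np.flatnonzero(in_window)
    return idx[(idx >= lo_ok) & (idx <= hi_ok)]


def _pair_arrays(epochs: Epochs, chan_a: int, chan_b: int, config: GCConfig):
    if abs(epochs.fs - config.fs) > 1e-9:
        raise ValueError(f"epochs must be sampled at {config.fs} Hz; resample first")
    if chan_a == chan_b:
        raise ValueError("Granger causality of a channel on itself is undefined")
    keep = epochs.valid
    A = epochs.data[chan_a][keep]
    B = epochs.data[chan_b][keep]
    min_seg = config.n_lags + 1
    if A.shape[1] < min_seg:
        raise ValueError("epochs shorter than n_lags + 1 samples")
    return A, B


def spectral_gc(
    x: np.ndarray, y: np.ndarray, config: GCConfig = GCConfig()
) -> float:
    """Band-averaged spectral GC(x -> y) from one pooled VAR fit.

    ``x``/``y`` are (trials, samples) arrays on a common trial set.  This is
    the single-window variant (the whole segment is one fit); the
    per-timepoint series lives in :func:`net_granger`.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    if x.shape != y.shape:
        raise ValueError("x and y must share shape (trials, samples)")
    if x is y or np.array_equal(x, y):
        raise ValueError("Granger causality of a channel on itself is undefined")
    p = config.n_lags
    T = x.shape[1]
    if T <= p + 1:
        raise ValueError("segment too short for the requested lag order")
    cfg = GCConfig(
        n_lags=p,
        band=config.band,
        fs=config.fs,
        window_samples=(T - 2 * p) // 2 * 2 + 1,
        n_freqs=config.n_freqs,
        literal_eq=config.literal_eq,
    )
    center = np.array([T // 2])
    half = (cfg.window_samples - 1) // 2
    center = np.clip(center, p + half, T - 1 - half)
    Za = _series_stack(x, p)
    Zb = _series_stack(y, p)
    G = np.empty((2 * (p + 1), 2 * (p + 1), T))
    a_idx = np.r_[0, np.arange(2, p + 2)]
    b_idx = np.r_[1, np.arange(p + 2, 2 * p + 2)]
    Gaa = np.einsum("uit,vit->uvt", Za, Za)
    Gbb = np.einsum("uit,vit->uvt", Zb, Zb)
    Gab = np.einsum("uit,vit->uvt", Za, Zb)
    G[np.ix_(a_idx, a_idx)] = Gaa
    G[np.ix_(b_idx, b_idx)] = Gbb
    G[np.ix_(a_idx, b_idx)] = Gab
    G[np.ix_(b_idx, a_idx)] = np.swapaxes(Gab, 0, 1)
    M = np.moveaxis(_window_sums(G, center, half), -1, 0)
    n_rows = x.shape[0] * cfg.window_samples
    gc_ab, _ = _gc_from_products(M, n_rows, p, cfg.freq_grid, cfg.fs)
    return float(gc_ab.mean())


def net_granger(
    epochs: Epochs,
    chan_a: int,
    chan_b: int,
    config: GCConfig = GCConfig(),
    labels: Optional[tuple[str, str]] = None,
) -> NetGrangerSeries:
    """Per-timepoint net time-reversed GC series for one channel pair."""
    A, B = _pair_arrays(epochs, chan_a, chan_b, config)
    centers = _analysis_centers(epochs, config)
    net = _net_gc(A, B, config, centers)[0]
    return NetGrangerSeries(
        pair=labels or (f"ch{chan_a}", f"ch{chan_b}"),
        net=net,
        times_ms=epochs.times_ms[centers],
        fs=config.fs,
    )


def gc_permutation_test(
    epochs: Epochs,
    chan_a: int,
    chan_b: int,
    config: GCConfig = GCConfig(),
    seed: int = 0,
    labels: Optional[tuple[str, str]] = None,
) -> NetGrangerSeries:
    """Net-GC series with trial-shuffle significance and the duration rule.

    Two-sided p per timepoint from |net| against the shuffled null,
    Benjamini-Hochberg across timepoints, and the pair qualifies when more
    than ``duration_ms`` worth of timepoints (50 at 100 Hz for 500 ms) are
    significant.
    """
    if config.n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    A, B = _pair_arrays(epochs, chan_a, chan_b, config)
    centers = _analysis_centers(epochs, config)
    n_trials = A.shape[0]
    perms = np.stack([rng.permutation(n_trials) for _ in range(config.n_perm)])
    all_net = _net_gc(A, B, config, centers, perms=perms)
    observed, null = all_net[0], all_net[1:]
    p_raw = (1.0 + (np.abs(null) >= np.abs(observed)).sum(axis=0)) / (
        config.n_perm + 1.0
    )
    p_corr = multipletests(p_raw, alpha=config.alpha, method="fdr_bh")[1]
    sig = p_corr < config.alpha
    n_sig = int(sig.sum())
    thr = config.duration_samples
    qualifies = bool(np.isfinite(thr) and n_sig > thr)
    return NetGrangerSeries(
        pair=labels or (f"ch{chan_a}", f"ch{chan_b}"),
        net=observed,
        times_ms=epochs.times_ms[centers],
        fs=config.fs,
        p_corrected=p_corr,
        sig_mask=sig,
        qualifies=qualifies,
        n_sig=n_sig,
    )


# ---------------------------------------------------------------------------
# Cross-correlation lag analysis


def concat_approach(
    data: np.ndarray,
    times_ms: np.ndarray,
    windows_ms: Sequence[tuple[float, float]],
) -> tuple[np.ndarray, list[tuple[int, int]], list[int]]:
    """Concatenate per-trial approach windows into one sequence per channel.

    ``data`` is (channels, trials, samples) theta-band signal on the
    ``times_ms`` axis; ``windows_ms`` gives each trial's (movement onset,
    turnaround) span.  Trials with an empty window are dropped (their ids
    are returned).  Returns (channels x total samples, per-trial boundary
    index, dropped trial ids).
    """
    chunks: list[np.ndarray] = []
    boundaries: list[tuple[int, int]] = []
    dropped: list[int] = []
    pos = 0
    for t, (lo, hi) in enumerate(windows_ms):
        sel = (times_ms >= lo) & (times_ms < hi)
        n = int(sel.sum())
        if n == 0:
            dropped.append(t)
            continue
        chunks.append(data[:, t, sel])
        boundaries.append((pos, pos + n))
        pos += n
    if not chunks:
        raise ValueError("no trial retained an approach window")
    return np.concatenate(chunks, axis=-1), boundaries, dropped


def _ccf(a: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray:
    """Pearson correlation of a[t] with b[t+k] for k in [-max_lag, max_lag]."""
    out = np.empty(2 * max_lag + 1)
    n = a.size
    for i, k in enumerate(range(-max_lag, max_lag + 1)):
        if k >= 0:
            x, y = a[: n - k], b[k:]
        else:
            x, y = a[-k:], b[: n + k]
        out[i] = np.corrcoef(x, y)[0, 1]
    return out


def _permute_segments(
    x: np.ndarray, boundaries: list[tuple[int, int]], perm: np.ndarray
) -> np.ndarray:
    """Reorder trial segments while keeping each slot's length constant."""
    out = np.empty_like(x)
    for slot, src in zip(boundaries, perm):
        lo, hi = slot
        s_lo, s_hi = boundaries[src]
        seg = x[s_lo:s_hi]
        need = hi - lo
        if seg.size < need:  # wrap-pad shorter segments
            seg = np.resize(seg, need)
        out[lo:hi] = seg[:need]
    return out


def cross_correlation_test(
    concat_a: np.ndarray,
    concat_b: np.ndarray,
    boundaries: list[tuple[int, int]],
    seed: int = 0,
    max_lag: int = 25,
    n_perm: int = 200,
    fs: float = 100.0,
    labels: tuple[str, str] = ("a", "b"),
) -> CrossCorrResult:
    """CCF over +/-25 lags with a trial-length-preserving shuffle null.

    ``best_lag > 0`` means channel a leads channel b.  The best lag is
    retained only if the peak |correlation| is in the top 5% of the null.
    """
    if len(boundaries) < 3:
        raise ValueError("need at least 3 trials for the shuffle null")
    rng = np.random.default_rng(seed)
    corr = _ccf(concat_a, concat_b, max_lag)
    best_idx = int(np.argmax(np.abs(corr)))
    lags = np.arange(-max_lag, max_lag + 1)
    max_corr = float(corr[best_idx])
    null = np.empty(n_perm)
    n_tr = len(boundaries)
    for k in range(n_perm):
        perm = rng.permutation(n_tr)
        b_perm = _permute_segments(concat_b, boundaries, perm)
        null[k] = np.max(np.abs(_ccf(concat_a, b_perm, max_lag)))
    p = (1.0 + (null >= abs(max_corr)).sum()) / (n_perm + 1.0)
    return CrossCorrResult(
        pair=labels,
        lags=lags,
        corr=corr,
        best_lag=int(lags[best_idx]),
        best_lag_ms=float(lags[best_idx] / fs * 1000.0),
        max_corr=max_corr,
        p_value=float(p),
        retained=bool(p <= 0.05),
        n_perm=n_perm,
    )


def direction_consensus(
    region_pair: tuple[str, str],
    p_pos_granger: Optional[float],
    p_pos_ccf: Optional[float],
    threshold: float = 0.95,
) -> DirectionalPair:
    """Dual-method consensus: both P+ beyond the threshold in the same
    direction.  A missing method leaves the consensus undefined (None)."""
    return DirectionalPair(
        region_pair=region_pair,
        p_pos_granger=p_pos_granger,
        p_pos_ccf=p_pos_ccf,
        threshold=threshold,
    )
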