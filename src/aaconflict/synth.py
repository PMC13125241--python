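"""Trial-structured synthetic LFP with a known coupling answer key.

Each channel is the sum of

* spectrally shaped 1/f background noise (default exponent 1.0),
* a stochastic theta oscillator — an AR(2) process with spectral peak at
  5 Hz and pole radius 0.95, so band coherence stays below 1 and
  permutation nulls are meaningful — whose amplitude follows a per-epoch
  schedule around the turnaround event (elevated during approach, reduced
  during avoidance),
* lagged, gain-weighted copies of source-channel oscillators for every
  entry of the ground-truth coupling list, and
* optional high-frequency bursts (80-120 Hz filtered noise under a 300-ms
  raised-cosine envelope) anchored to an event such as attack onset.

Every trial segment is prefixed with an inter-trial interval used as the
power-normalisation baseline.  Event times are stored in ms from segment
start.  Datasets round-trip through an HDF5 container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np
from scipy import signal as sps

from .task import TrialLog

__all__ = [
    "ChannelInfo",
    "Coupling",
    "HFAEvent",
    "GroundTruth",
    "LFPDataset",
    "generate_dataset",
    "inject_zero_lag_mixing",
    "make_fixture",
    "make_simple_logs",
]

REGIONS = ("HC", "AMY", "OFC", "ACC", "MFG")
SUPPORTED_FS = (512.0, 1000.0, 2000.0)


@dataclass(frozen=True)
class ChannelInfo:
    channel_id: str
    region: str
    hemisphere: str = "left"


@dataclass(frozen=True)
class Coupling:
    source: str
    target: str
    lag_ms: float
    gain: float

    def __post_init__(self) -> None:
        if self.lag_ms < 0:
            raise ValueError("lag_ms must be non-negative")
        if self.gain < 0:
            raise ValueError("gain must be non-negative")


@dataclass(frozen=True)
class HFAEvent:
    channel: str
    anchor: str  # event name, e.g. "attack_onset"
    amplitude: float
    duration_ms: float = 300.0


@dataclass
class GroundTruth:
    """Statistical structure planted in a synthetic dataset."""

    channels: list[ChannelInfo]
    couplings: list[Coupling] = field(default_factory=list)
    theta_schedule: dict[str, float] = field(
        default_factory=lambda: {"approach": 1.0, "avoid": 1.0}
    )
    hfa_events: list[HFAEvent] = field(default_factory=list)
    zero_lag_mixing: Optional[np.ndarray] = None
    background_exponent: float = 1.0
    theta_peak_hz: float = 5.0
    theta_pole_radius: float = 0.95

    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels]

    def validate(self) -> None:
        ids = set(self.channel_ids())
        for c in self.couplings:
            if c.source not in ids or c.target not in ids:
                raise ValueError(f"coupling {c} references unknown channel")
        if self.zero_lag_mixing is not None:
            m = np.asarray(self.zero_lag_mixing)
            if m.shape != (len(ids), len(ids)):
                raise ValueError("mixing matrix dimension must equal channel count")
            if abs(np.linalg.det(m)) < 1e-12:
                raise ValueError("mixing matrix must be invertible")


@dataclass
class LFPDataset:
    """Channels x trials x samples array with event annotations."""

    signal: np.ndarray
    fs: float
    channels: list[ChannelInfo]
    events: list[dict]  # per-trial dict of event name -> time (ms) or None
    ground_truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        if self.fs not in SUPPORTED_FS:
            raise ValueError(f"fs must be one of {SUPPORTED_FS}")
        if np.isnan(self.signal).any():
            raise ValueError("signal contains NaNs")
        n_ch, n_tr, n_samp = self.signal.shape
        if n_ch != len(self.channels) or n_tr != len(self.events):
            raise ValueError("signal shape inconsistent with metadata")
        dur_ms = n_samp / self.fs * 1000.0
        for ev in self.events:
            for name, t in ev.items():
                if t is not None and not (0 <= t <= dur_ms):
                    raise ValueError(f"event {name}={t} outside trial duration")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_trials(self) -> int:
        return self.signal.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[2]

    def channel_index(self, channel_id: str) -> int:
        for i, ch in enumerate(self.channels):
            if ch.channel_id == channel_id:
                return i
        raise KeyError(channel_id)

    # -- HDF5 container ----------------------------------------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=self.signal)
            f.attrs["fs"] = self.fs
            chans = [(c.channel_id, c.region, c.hemisphere) for c in self.channels]
            f.create_dataset(
                "channels", data=np.array(chans, dtype=h5py.string_dtype())
            )
            f.attrs["events_json"] = json.dumps(self.events)

    @classmethod
    def load(cls, path) -> "LFPDataset":
        with h5py.File(path, "r") as f:
            signal = f["signal"][()]
            fs = float(f.attrs["fs"])
            chans = [
                ChannelInfo(*(s.decode() for s in row)) for row in f["channels"][()]
            ]
            events = json.loads(f.attrs["events_json"])
        return cls(signal=signal, fs=fs, channels=chans, events=events)


def _one_over_f_noise(
    n_samples: int, fs: float, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, unit variance."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n=n_samples)
    return shaped / shaped.std()


def _ar2_oscillator(
    n_samples: int, fs: float, peak_hz: float, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Stochastic narrowband oscillator: AR(2) with poles at radius*e^{±iw}."""
    w = 2.0 * np.pi * peak_hz / fs
    a1 = 2.0 * radius * np.cos(w)
    a2 = -(radius**2)
    burn = 500
    e = rng.standard_normal(n_samples + burn)
    x = sps.lfilter([1.0], [1.0, -a1, -a2], e)[burn:]
    return x / x.std()


def _raised_cosine(n: int) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / max(n - 1, 1)))


def _theta_envelope(
    n_samples: int, fs: float, events: dict, schedule: dict[str, float]
) -> np.ndarray:
    """Amplitude envelope: approach multiplier before the turnaround, avoid
    multiplier after, with a 200-ms smooth transition; ITI kept at the avoid
    level."""
    env = np.full(n_samples, schedule.get("avoid", 1.0))
    onset = events.get("movement_onset")
    turn = events.get("turnaround")
    if onset is not None and turn is not None:
        i0 = int(onset / 1000.0 * fs)
        i1 = int(turn / 1000.0 * fs)
        env[i0:i1] = schedule.get("approach", 1.0)
        ramp = int(0.2 * fs)
        for edge in (i0, i1):
            a, b = max(edge - ramp // 2, 0), min(edge + ramp // 2, n_samples)
            if b > a:
                left = env[a - 1] if a > 0 else env[a]
                right = env[b] if b < n_samples else env[b - 1]
                env[a:b] = np.linspace(left, right, b - a)
    return env


def generate_dataset(
    ground_truth: GroundTruth,
    logs: Sequence[TrialLog] | Sequence[dict],
    fs: float = 1000.0,
    snr: float = 1.0,
    seed: int = 0,
    iti_ms: float = 1500.0,
) -> LFPDataset:
    """Synthesize an LFP dataset with the structure declared in ``ground_truth``.

    ``logs`` supply per-trial event times, either TrialLog objects or dicts
    with keys movement_onset / turnaround / attack_onset / trial_end (ms,
    relative to trial onset).  ``snr`` is the oscillator-to-background
    amplitude ratio.  Each trial segment is [ITI | trial] and all event
    times in the returned dataset are relative to segment start.
    """
    ground_truth.validate()
    rng = np.random.default_rng(seed)
    events = [_log_events(lg, iti_ms) for lg in logs]
    max_end = max(ev["trial_end"] for ev in events)
    n_samples = int(np.ceil(max_end / 1000.0 * fs)) + 1
    ids = ground_truth.channel_ids()
    n_ch, n_tr = len(ids), len(events)

    max_lag = max((c.lag_ms for c in ground_truth.couplings), default=0.0)
    if max_lag / 1000.0 * fs >= n_samples:
        raise ValueError("coupling lag exceeds trial duration")

    osc = np.empty((n_ch, n_tr, n_samples))
    for i in range(n_ch):
        for t in range(n_tr):
            osc[i, t] = _ar2_oscillator(
                n_samples,
                fs,
                ground_truth.theta_peak_hz,
                ground_truth.theta_pole_radius,
                rng,
            )

    # Coupled component: target receives a delayed, scaled copy of the
    # source oscillator (added before amplitude scheduling).
    coupled = osc.copy()
    for c in ground_truth.couplings:
        si, ti = ids.index(c.source), ids.index(c.target)
        lag = int(round(c.lag_ms / 1000.0 * fs))
        shifted = np.zeros_like(osc[si])
        if lag == 0:
            shifted[:] = osc[si]
        else:
            shifted[:, lag:] = osc[si][:, :-lag]
        coupled[ti] = coupled[ti] + c.gain * shifted

    data = np.empty_like(coupled)
    for t in range(n_tr):
        env = _theta_envelope(n_samples, fs, events[t], ground_truth.theta_schedule)
        for i in range(n_ch):
            background = _one_over_f_noise(
                n_samples, fs, ground_truth.background_exponent, rng
            )
            data[i, t] = snr * env * coupled[i, t] + background

    # HFA bursts anchored to events.
    nyq = fs / 2.0
    if ground_truth.hfa_events:
        sos = sps.butter(4, [80.0 / nyq, min(120.0, nyq * 0.95) / nyq], "bandpass", output="sos")
        for ev_spec in ground_truth.hfa_events:
            ci = ids.index(ev_spec.channel)
            n_burst = int(ev_spec.duration_ms / 1000.0 * fs)
            win = _raised_cosine(n_burst)
            for t in range(n_tr):
                anchor = events[t].get(ev_spec.anchor)
                if anchor is None:
                    continue
                i0 = int(anchor / 1000.0 * fs)
                i1 = min(i0 + n_burst, n_samples)
                burst = sps.sosfilt(sos, rng.standard_normal(n_burst + 200))[200:]
                burst = burst / burst.std()
                data[ci, t, i0:i1] += ev_spec.amplitude * (win * burst)[: i1 - i0]

    ds = LFPDataset(
        signal=data,
        fs=fs,
        channels=list(ground_truth.channels),
        events=events,
        ground_truth=ground_truth,
    )
    if ground_truth.zero_lag_mixing is not None:
        ds = inject_zero_lag_mixing(ds, ground_truth.zero_lag_mixing)
    return ds


def _log_events(log, iti_ms: float) -> dict:
    if isinstance(log, TrialLog):
        ev = {
            "movement_onset": log.movement_onset,
            "turnaround": log.final_turnaround,
            "attack_onset": log.attack_onset,
            "trial_end": log.trial_end,
        }
    else:
        ev = dict(log)
    out = {"iti_end": iti_ms}
    for name in ("movement_onset", "turnaround", "attack_onset", "trial_end"):
        t = ev.get(name)
        out[name] = None if t is None else float(t) + iti_ms
    if out["trial_end"] is None:
        raise ValueError("every trial log must define trial_end")
    return out


def inject_zero_lag_mixing(dataset: LFPDataset, mixing: np.ndarray) -> LFPDataset:
    """Replace signals by instantaneous linear mixtures (volume-conduction
    surrogate).  Event metadata is unchanged."""
    mixing = np.asarray(mixing, dtype=float)
    n = dataset.n_channels
    if mixing.shape != (n, n):
        raise ValueError("mixing matrix dimension must equal channel count")
    if abs(np.linalg.det(mixing)) < 1e-12:
        raise ValueError("mixing matrix is singular")
    mixed = np.einsum("ij,jts->its", mixing, dataset.signal)
    return LFPDataset(
        signal=mixed,
        fs=dataset.fs,
        channels=list(dataset.channels),
        events=list(dataset.events),
        ground_truth=dataset.ground_truth,
    )


def make_simple_logs(
    n_trials: int,
    trial_ms: float = 4000.0,
    movement_onset_ms: float = 500.0,
    turnaround_ms: float = 2500.0,
    attack_ms: Optional[float] = None,
    jitter_ms: float = 0.0,
    seed: int = 0,
) -> list[dict]:
    """Fixed-schedule event logs for fixtures (optionally jittered)."""
    rng = np.random.default_rng(seed)
    logs = []
    for _ in range(n_trials):
        j = rng.uniform(-jitter_ms, jitter_ms) if jitter_ms else 0.0
        logs.append(
            {
                "movement_onset": movement_onset_ms,
                "turnaround": turnaround_ms + j,
                "attack_onset": attack_ms,
                "trial_end": trial_ms,
            }
        )
    return logs


def _channels(n: int, regions: Sequence[str] = REGIONS, hemis=None) -> list[ChannelInfo]:
    out = []
    for i in range(n):
        hemi = hemis[i] if hemis is not None else ("left" if i % 2 == 0 else "right")
        out.append(ChannelInfo(f"ch{i:02d}", regions[i % len(regions)], hemi))
    return out


def make_fixture(name: str, seed: int = 0, n_trials: int = 40, fs: float = 1000.0) -> LFPDataset:
    """Small canned datasets used throughout the test suite.

    * ``null`` — independent channels, flat theta schedule, no couplings.
    * ``coupled_lagged`` — ch00 drives ch01 at lag 25 ms, gain 0.8.
    * ``task_modulated`` — theta amplitude 2:1 approach:avoid, no couplings.
    * ``attack_hfa`` — HFA bursts after attack onset only in right-MFG
      channels.
    """
    logs = make_simple_logs(n_trials, seed=seed)
    if name == "null":
        gt = GroundTruth(channels=_channels(8))
    elif name == "coupled_lagged":
        gt = GroundTruth(
            channels=_channels(4),
            couplings=[Coupling("ch00", "ch01", lag_ms=25.0, gain=0.8)],
        )
    elif name == "task_modulated":
        gt = GroundTruth(
            channels=_channels(5),
            theta_schedule={"approach": 2.0, "avoid": 1.0},
        )
    elif name == "attack_hfa":
        chans = [
            ChannelInfo("mfg_r0", "MFG", "right"),
            ChannelInfo("mfg_r1", "MFG", "right"),
            ChannelInfo("mfg_l0", "MFG", "left"),
            ChannelInfo("hc_l0", "HC", "left"),
        ]
        gt = GroundTruth(
            channels=chans,
            hfa_events=[
                HFAEvent("mfg_r0", "attack_onset", amplitude=4.0),
                HFAEvent("mfg_r1", "attack_onset", amplitude=4.0),
            ],
        )
        logs = make_simple_logs(n_trials, attack_ms=2000.0, seed=seed)
    else:
        raise ValueError(f"unknown fixture {name!r}")
    return generate_dataset(gt, logs, fs=fs, snr=1.0, seed=seed)
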