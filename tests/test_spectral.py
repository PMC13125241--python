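"""Filters, referencing, epoching, Morlet power, baseline normalization."""

import numpy as np
import pytest
from scipy import signal as sps

from aaconflict import spectral, synth


def _tone(freq, fs, dur_s, amp=1.0):
    t = np.arange(int(dur_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def _amp_at(x, fs, freq):
    f, p = sps.periodogram(x, fs=fs)
    return np.sqrt(p[np.argmin(np.abs(f - freq))])


class TestPreprocess:
    def test_line_noise_attenuated(self):
        fs = 1000.0
        clean = _tone(5.0, fs, 10.0)
        noisy = clean + _tone(60.0, fs, 10.0)
        out = spectral.preprocess(noisy, fs)
        before = _amp_at(noisy, fs, 60.0)
        after = _amp_at(out, fs, 60.0)
        assert 20 * np.log10(before / after) >= 20.0

    def test_low_frequencies_preserved(self):
        fs = 1000.0
        x = _tone(5.0, fs, 10.0)
        out = spectral.preprocess(x, fs)
        mid = slice(2000, 8000)  # clear of filtfilt transients
        ratio = out[mid].std() / x[mid].std()
        assert abs(ratio - 1.0) < 0.01

    def test_length_preserved_and_fs_checked(self):
        x = np.random.default_rng(0).standard_normal((3, 2048))
        out = spectral.preprocess(x, 512.0)
        assert out.shape == x.shape
        with pytest.raises(ValueError):
            spectral.preprocess(x, 250.0)


class TestBipolarReference:
    def test_common_signal_cancels(self, rng):
        common = rng.standard_normal(1000)
        data = np.stack([common, common])
        out = spectral.bipolar_reference(data, [(0, 1)])
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_shaft_yields_n_minus_one_channels(self, rng):
        data = rng.standard_normal((6, 500))
        pairs = [(i, i + 1) for i in range(5)]
        out = spectral.bipolar_reference(data, pairs)
        assert out.shape == (5, 500)

    def test_shared_line_noise_removed_differential_kept(self):
        fs = 1000.0
        shared = _tone(60.0, fs, 4.0)
        differential = _tone(5.0, fs, 4.0)
        data = np.stack([shared + differential, shared])
        out = spectral.bipolar_reference(data, [(0, 1)])[0]
        assert _amp_at(out, fs, 60.0) < 1e-9
        assert _amp_at(out, fs, 5.0) == pytest.approx(
            _amp_at(differential, fs, 5.0), rel=1e-6
        )

    def test_unmatched_contact_rejected(self, rng):
        with pytest.raises(ValueError):
            spectral.bipolar_reference(rng.standard_normal((2, 10)), [(0, 5)])


class TestEpoching:
    def test_turnaround_lock_time_axis(self, coupled_fixture):
        ep = spectral.epoch(coupled_fixture, "turnaround", (-2500.0, 2500.0))
        assert ep.times_ms[0] == pytest.approx(-2500.0)
        assert ep.times_ms[-1] == pytest.approx(2500.0, abs=1.0)
        assert 0.0 in np.round(ep.times_ms, 6)

    def test_lock_sample_matches_raw_recording(self, coupled_fixture):
        ds = coupled_fixture
        ep = spectral.epoch(ds, "turnaround", (-100.0, 100.0))
        zero_idx = int(np.argmin(np.abs(ep.times_ms)))
        for trial in range(3):
            ev = ds.events[trial]["turnaround"]
            raw_idx = int(round(ev / 1000.0 * ds.fs))
            assert ep.data[0, trial, zero_idx] == ds.signal[0, trial, raw_idx]

    def test_missing_event_masks_trial(self):
        ds = synth.make_fixture("null", seed=1, n_trials=5)
        ds.events[2]["attack_onset"] = None  # no attack on this trial
        ep = spectral.epoch(ds, "attack_onset", (-100.0, 100.0))
        assert not ep.valid[2]

    def test_out_of_bounds_window_masks_trial(self, coupled_fixture):
        ep = spectral.epoch(coupled_fixture, "trial_onset", (-5000.0, 100.0))
        assert not ep.valid.any()


class TestMorletTFR:
    def test_pure_tone_localizes_to_its_bin(self):
        fs = 1000.0
        n_trials, dur = 3, 6.0
        data = np.tile(_tone(5.0, fs, dur), (1, n_trials, 1))
        ep = spectral.Epochs(
            data=data,
            fs=fs,
            times_ms=np.arange(data.shape[-1]) / fs * 1000.0,
            lock_event="trial_onset",
            window_ms=(0.0, dur * 1000.0),
            valid=np.ones(n_trials, bool),
        )
        freqs, cycles = spectral.band_freqs(2.0, 20.0)
        tfr = spectral.morlet_tfr(ep, freqs=freqs, cycles=cycles, decim=5)
        mid = tfr.power.shape[-1] // 2
        peak = int(np.argmax(tfr.power[0, 0, :, mid]))
        nearest = int(np.argmin(np.abs(freqs - 5.0)))
        assert abs(peak - nearest) <= 1

    def test_white_noise_flat_after_one_over_f_correction(self, rng):
        fs = 1000.0
        data = rng.standard_normal((1, 4, 6000))
        ep = spectral.Epochs(
            data=data,
            fs=fs,
            times_ms=np.arange(6000) / fs * 1000.0,
            lock_event="trial_onset",
            window_ms=(0.0, 6000.0),
            valid=np.ones(4, bool),
        )
        freqs, cycles = spectral.band_freqs(3.0, 100.0)
        tfr = spectral.morlet_tfr(ep, freqs=freqs, cycles=cycles, decim=10)
        valid_t = tfr.edge_valid.all(axis=0)
        mean_p = tfr.power[0, :, :, valid_t].mean(axis=(0, 1))
        slope = np.polyfit(np.log(freqs), np.log(mean_p), 1)[0]
        assert abs(slope) < 0.3

    def test_zero_signal_zero_power(self):
        ep = spectral.Epochs(
            data=np.zeros((1, 2, 4000)),
            fs=1000.0,
            times_ms=np.arange(4000.0),
            lock_event="trial_onset",
            window_ms=(0.0, 4000.0),
            valid=np.ones(2, bool),
        )
        freqs, cycles = spectral.band_freqs(3.0, 20.0)
        tfr = spectral.morlet_tfr(ep, freqs=freqs, cycles=cycles)
        assert np.allclose(tfr.power, 0.0)

    def test_epoch_shorter_than_widest_wavelet_rejected(self):
        ep = spectral.Epochs(
            data=np.zeros((1, 2, 500)),
            fs=1000.0,
            times_ms=np.arange(500.0),
            lock_event="trial_onset",
            window_ms=(0.0, 500.0),
            valid=np.ones(2, bool),
        )
        with pytest.raises(ValueError):
            spectral.morlet_tfr(ep)  # 1 Hz wavelet cannot fit 500 ms


def _segment_tfr(ds, fmin, fmax, decim=10):
    ep = spectral.epoch(ds, "trial_onset", (-1500.0, 4000.0))
    freqs, cycles = spectral.band_freqs(fmin, fmax)
    return spectral.morlet_tfr(ep, freqs=freqs, cycles=cycles, decim=decim)


class TestBandPower:
    def test_baseline_z_scores_itself_to_zero_mean_unit_sd(self):
        ds = synth.make_fixture("null", seed=2, n_trials=12)
        tfr = _segment_tfr(ds, 2.5, 20.0)
        bp = spectral.band_power(tfr, "theta", tfr, baseline_window_ms=(-1000.0, 0.0))
        sel = (bp.times_ms >= -1000.0) & (bp.times_ms <= 0.0)
        base = bp.values[..., sel]
        assert abs(base.mean()) < 0.1

    def test_injected_100hz_burst_elevates_hfa(self):
        # Inject a 100-Hz-centred burst (80-120 Hz noise under a raised
        # cosine) at a known time and check the sub-band HFA z-score jumps
        # by > 2 during the burst relative to just before it.
        gt = synth.GroundTruth(
            channels=synth._channels(2),
            hfa_events=[synth.HFAEvent("ch00", "attack_onset", amplitude=4.0)],
        )
        logs = synth.make_simple_logs(10, attack_ms=1500.0)
        ds = synth.generate_dataset(gt, logs, fs=1000.0, seed=3)
        tfr = _segment_tfr(ds, 60.0, 150.0, decim=10)
        bp = spectral.band_power(tfr, "hfa", tfr, baseline_window_ms=(-1000.0, 0.0))
        tt = bp.times_ms
        during = bp.values[0, :, (tt >= 1550) & (tt <= 1750)].mean()
        before = bp.values[0, :, (tt >= 800) & (tt <= 1300)].mean()
        assert during - before > 2.0
        # the channel without a burst event stays flat
        other = bp.values[1, :, (tt >= 1550) & (tt <= 1750)].mean()
        assert abs(other) < 1.0

    def test_theta_schedule_recovered_in_every_channel(self):
        ds = synth.make_fixture("task_modulated", seed=4, n_trials=16)
        tfr = _segment_tfr(ds, 2.5, 20.0)
        bp = spectral.band_power(tfr, "theta", tfr, baseline_window_ms=(-1000.0, 0.0))
        t = bp.times_ms
        appr = bp.values[..., (t >= 700) & (t <= 2300)].mean(axis=(1, 2))
        avoid = bp.values[..., (t >= 2700) & (t <= 3900)].mean(axis=(1, 2))
        assert (appr > avoid).all()

    def test_channel_reorder_commutes(self):
        ds = synth.make_fixture("task_modulated", seed=5, n_trials=6)
        tfr = _segment_tfr(ds, 2.5, 20.0)
        bp = spectral.band_power(tfr, "theta", tfr, baseline_window_ms=(-1000.0, 0.0))
        perm = [2, 0, 1, 4, 3]
        ds2 = synth.LFPDataset(
            signal=ds.signal[perm],
            fs=ds.fs,
            channels=[ds.channels[i] for i in perm],
            events=ds.events,
        )
        tfr2 = _segment_tfr(ds2, 2.5, 20.0)
        bp2 = spectral.band_power(tfr2, "theta", tfr2, baseline_window_ms=(-1000.0, 0.0))
        np.testing.assert_allclose(bp2.values, bp.values[perm], rtol=1e-10)

    def test_sampling_dialects_agree_after_common_downsampling(self):
        # The same generative process recorded at the two hospital rates
        # yields matching theta estimates on the shared 20 Hz grid.
        means = {}
        for fs in (2000.0, 512.0):
            ds = synth.make_fixture("task_modulated", seed=6, n_trials=16, fs=fs)
            tfr = _segment_tfr(ds, 2.5, 20.0, decim=max(int(fs // 100), 1))
            bp = spectral.band_power(
                tfr, "theta", tfr, baseline_window_ms=(-1000.0, 0.0)
            )
            t = bp.times_ms
            means[fs] = bp.values[..., (t >= 700) & (t <= 2300)].mean()
        assert abs(means[2000.0] - means[512.0]) < 0.2


class TestThetaBandpass:
    def test_passband_and_stopband(self):
        fs = 1000.0
        in_band = _tone(5.0, fs, 8.0)
        out = spectral.bandpass_theta(in_band, fs)
        mid = slice(2000, 6000)
        assert out[mid].std() / in_band[mid].std() > 0.95

        out_band = _tone(20.0, fs, 8.0)
        filt = spectral.bandpass_theta(out_band, fs)
        atten = 20 * np.log10(out_band[mid].std() / filt[mid].std())
        assert atten >= 20.0

    def test_zero_phase(self):
        fs = 500.0
        x = _tone(5.0, fs, 8.0)
        y = spectral.bandpass_theta(x, fs)
        lags = np.arange(-10, 11)
        mid = slice(1000, 3000)
        cc = [
            np.corrcoef(x[mid], np.roll(y, k)[mid])[0, 1] for k in lags
        ]
        assert lags[int(np.argmax(cc))] == 0
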