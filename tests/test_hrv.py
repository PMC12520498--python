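"""Cardiac branch: Butterworth band-pass, Pan-Tompkins detection, IBI
correction, SPWVD spectrogram, windowed band power and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import welch

from brainheart import hrv
from brainheart.datatypes import EcgSignal, HrvMetricSeries, HrvSpectrogram, IbiSeries
from brainheart.synth import (
    OscillatorSpec,
    SdgSimConfig,
    generate_ecg_from_beats,
    generate_rr_ipfm,
)


def sine_ecg(freq, fs=1000.0, duration=10.0, amp=100.0):
    t = np.arange(int(duration * fs)) / fs
    return EcgSignal(amp * np.sin(2 * np.pi * freq * t), fs)


class TestBandpass:
    def test_stopband_rejection_at_60hz(self):
        # steady state: skip the slow settling of the 0.5 Hz high-pass edge
        sig = sine_ecg(60.0, duration=60.0)
        out = hrv.bandpass_ecg(sig, 0.5, 30.0)
        core = slice(5000, -5000)
        assert np.std(out.samples[core]) < 0.05 * np.std(sig.samples[core])

    def test_passband_unity_at_10hz(self):
        sig = sine_ecg(10.0, duration=60.0)
        out = hrv.bandpass_ecg(sig, 0.5, 30.0)
        core = slice(5000, -5000)
        assert abs(np.std(out.samples[core]) / np.std(sig.samples[core]) - 1) < 0.05

    def test_white_noise_band_limited(self, rng):
        sig = EcgSignal(rng.standard_normal(60000), 1000.0)
        out = hrv.bandpass_ecg(sig, 0.5, 30.0)
        f, p = welch(out.samples, fs=1000.0, nperseg=4096)
        assert p[f > 35].sum() < 0.01 * p.sum()

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            hrv.bandpass_ecg(sine_ecg(10.0, fs=100.0), 0.5, 60.0)


class TestDetect:
    def test_sixty_bpm_sixty_peaks(self):
        cfg = SdgSimConfig(mean_hr=60.0, lf_osc=OscillatorSpec(0.1, 0.0),
                           hf_osc=OscillatorSpec(0.25, 0.0), noise_sd=0.0,
                           amplitude_jitter=0.0, seed=0)
        beats = generate_rr_ipfm(cfg, 60.0)
        ecg = generate_ecg_from_beats(beats, 1000.0)
        det = hrv.detect_r_peaks(ecg)
        assert abs(det.size - 60) <= 1

    def test_roundtrip_accuracy_under_modulation(self):
        cfg = SdgSimConfig(seed=5)
        beats = generate_rr_ipfm(cfg, 120.0)
        ecg = generate_ecg_from_beats(beats, 1000.0, noise_sd=10.0,
                                      rng=np.random.default_rng(0))
        det = hrv.detect_r_peaks(ecg)
        true = beats.beat_times
        err = np.abs(det[:, None] - true[None, :]).min(axis=1)
        assert np.median(err) < 0.010

    def test_detector_sensitivity_and_ppv(self):
        # clean synthetic ECG across 50-100 bpm
        for hr in (50.0, 75.0, 100.0):
            cfg = SdgSimConfig(mean_hr=hr, seed=int(hr))
            beats = generate_rr_ipfm(cfg, 120.0)
            ecg = generate_ecg_from_beats(beats, 500.0)
            det = hrv.detect_r_peaks(ecg)
            true = beats.beat_times
            d = np.abs(det[:, None] - true[None, :])
            hits = (d.min(axis=1) < 0.05).sum()
            assert hits / true.size >= 0.99  # sensitivity
            assert hits / det.size >= 0.99  # positive predictive value

    def test_flat_signal_warns_and_returns_nothing(self):
        sig = EcgSignal(np.zeros(10000), 1000.0)
        with pytest.warns(UserWarning):
            det = hrv.detect_r_peaks(sig)
        assert det.size == 0

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="5 s"):
            hrv.detect_r_peaks(EcgSignal(np.ones(1000), 1000.0))


class TestCorrectIbi:
    def test_deleted_beat_restored(self):
        times = np.arange(0.0, 30.0, 1.0)
        deleted = np.delete(times, 13)
        out = hrv.correct_ibi(deleted)
        assert (out.correction_flags == "interpolated").sum() == 1
        restored = out.beat_times[out.correction_flags == "interpolated"][0]
        assert abs(restored - 13.0) < 0.050

    def test_spurious_beat_removed(self):
        times = np.sort(np.append(np.arange(0.0, 30.0, 1.0), 10.2))
        out = hrv.correct_ibi(times)
        assert out.n_removed == 1
        iv = out.intervals
        assert np.all((iv >= 0.3) & (iv <= 2.0))

    def test_clean_beats_identity(self):
        times = np.arange(0.0, 30.0, 0.8)
        out = hrv.correct_ibi(times)
        np.testing.assert_array_equal(out.beat_times, times)
        assert np.all(out.correction_flags == "original")

    def test_high_correction_fraction_warns(self):
        times = np.delete(np.arange(0.0, 40.0, 1.0), [5, 7, 9, 11, 13, 15, 17, 19, 21, 23])
        with pytest.warns(UserWarning, match="corrected"):
            hrv.correct_ibi(times)

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError):
            hrv.correct_ibi(np.array([0.0, 1.0]))


class TestSpwvd:
    def test_constant_ibis_have_no_band_power(self):
        quiet = SdgSimConfig(mean_hr=70.0, lf_osc=OscillatorSpec(0.1, 0.0),
                             hf_osc=OscillatorSpec(0.25, 0.0), noise_sd=0.0,
                             amplitude_jitter=0.0, seed=0)
        mod = SdgSimConfig(mean_hr=70.0, lf_osc=OscillatorSpec(0.1, 0.058),
                           hf_osc=OscillatorSpec(0.25, 0.0), noise_sd=0.0,
                           amplitude_jitter=0.0, seed=0)  # ~50 ms IBI swing
        powers = []
        for cfg in (quiet, mod):
            spec = hrv.hrv_time_frequency(generate_rr_ipfm(cfg, 180.0))
            mask = (spec.freqs >= 0.04) & (spec.freqs <= 0.4)
            powers.append(spec.power[:, mask].sum())
        assert powers[0] < 0.01 * powers[1]

    def test_single_modulation_peak_matches_welch(self):
        cfg = SdgSimConfig(mean_hr=70.0, lf_osc=OscillatorSpec(0.1, 0.0),
                           hf_osc=OscillatorSpec(0.25, 0.08), noise_sd=0.0,
                           amplitude_jitter=0.0, seed=0)
        ibis = generate_rr_ipfm(cfg, 300.0)
        spec = hrv.hrv_time_frequency(ibis)
        avg = spec.power.mean(axis=0)
        peak = spec.freqs[np.argmax(avg)]
        beats = ibis.beat_times
        from scipy.interpolate import CubicSpline

        grid = np.arange(beats[1], beats[-1], 0.25)
        ser = CubicSpline(beats[1:], np.diff(beats))(grid)
        f, p = welch(ser - ser.mean(), fs=4.0, nperseg=512)
        assert abs(peak - f[np.argmax(p)]) <= max(spec.df, f[1] - f[0])

    def test_spectrogram_shape_and_positivity(self):
        spec = hrv.hrv_time_frequency(generate_rr_ipfm(SdgSimConfig(seed=1), 120.0))
        assert spec.freqs.size == 512
        assert spec.freqs[0] == 0.0 and spec.freqs[-1] < 0.5
        assert np.all(spec.power >= 0)

    def test_low_interp_rate_rejected(self):
        ib = generate_rr_ipfm(SdgSimConfig(seed=1), 120.0)
        with pytest.raises(ValueError, match="interp_rate"):
            hrv.hrv_time_frequency(ib, interp_rate=0.5)

    def test_short_record_rejected(self):
        ib = generate_rr_ipfm(SdgSimConfig(seed=1), 30.0)
        with pytest.raises(ValueError, match="60 s"):
            hrv.hrv_time_frequency(ib)


def synthetic_spectrogram(duration=1200.0, peak_freqs=(0.1,), weights=None):
    times = np.arange(0.0, duration + 0.25, 0.25)
    freqs = np.arange(512) / 1024.0
    power = np.zeros((times.size, freqs.size))
    weights = weights or [1.0] * len(peak_freqs)
    for f0, w in zip(peak_freqs, weights):
        j = int(np.argmin(np.abs(freqs - f0)))
        power[:, j] = w
    return HrvSpectrogram(times, freqs, power)


class TestBandPower:
    def test_all_power_at_lf_peak(self):
        spec = synthetic_spectrogram(300.0, (0.1,))
        s = hrv.band_power_series(spec, 60.0, 5.0)
        assert np.all(s.hf < 1e-12)
        assert np.all(s.lf / (s.lf + s.hf) > 0.95)

    def test_equal_power_ratio_one(self):
        spec = synthetic_spectrogram(300.0, (0.1, 0.25), [1.0, 1.0])
        s = hrv.band_power_series(spec, 60.0, 5.0)
        assert np.allclose(s.lf_hf, 1.0)

    def test_window_count_arithmetic(self):
        spec = synthetic_spectrogram(1200.0, (0.1,))
        s = hrv.band_power_series(spec, 60.0, 5.0)
        assert s.times.size == (1200 - 60) // 5 + 1 == 229

    def test_band_partition_sums_to_total(self, rng):
        times = np.arange(0.0, 120.0, 0.25)
        freqs = np.arange(512) / 1024.0
        power = rng.uniform(size=(times.size, freqs.size))
        power[:, (freqs < 0.04) | (freqs > 0.4)] = 0.0
        spec = HrvSpectrogram(times, freqs, power)
        lf = hrv.band_integral(spec, (0.04, 0.15), closed_right=False)
        hf = hrv.band_integral(spec, (0.15, 0.4), closed_right=True)
        total = power.sum(axis=1) * spec.df
        assert np.allclose(lf + hf, total, rtol=1e-2)

    def test_zero_hf_window_flagged_nan(self):
        spec = synthetic_spectrogram(300.0, (0.1,))
        s = hrv.band_power_series(spec, 60.0, 5.0)
        assert np.all(np.isnan(s.lf_hf))


def metric_series(vals):
    v = np.asarray(vals, dtype=float)
    t = np.arange(v.size, dtype=float)
    return HrvMetricSeries(t, v, v, v, window=60.0, step=5.0)


class TestNormalize:
    def test_simple_scaling(self):
        (out,) = hrv.minmax_normalize([metric_series([2.0, 4.0, 6.0])])
        np.testing.assert_allclose(out.lf, [0.0, 0.5, 1.0])

    def test_idempotent_on_unit_range(self):
        (out,) = hrv.minmax_normalize([metric_series([0.0, 0.25, 1.0])])
        (out2,) = hrv.minmax_normalize([out])
        np.testing.assert_allclose(out.lf, out2.lf)

    def test_pooled_scope_across_conditions(self):
        zen = metric_series([5.0, 7.0])
        ctl = metric_series([1.0, 3.0])
        z, c = hrv.minmax_normalize([zen, ctl])
        assert z.lf.max() == 1.0 and c.lf.min() == 0.0
        assert z.lf.min() > c.lf.max() - 1e-12  # ordering preserved

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
    )
    def test_affine_invariance(self, a, b):
        base = np.array([1.0, 2.5, 3.0, 7.0])
        (n1,) = hrv.minmax_normalize([metric_series(base)])
        (n2,) = hrv.minmax_normalize([metric_series(a * base + b)])
        np.testing.assert_allclose(n1.lf, n2.lf, atol=1e-9)

    def test_constant_series_rejected_by_name(self):
        with pytest.raises(ValueError, match="lf"):
            hrv.minmax_normalize([metric_series([1.0, 1.0, 1.0])])


class TestConditionMean:
    def test_exclusion_removes_breathing_epoch(self):
        t = np.arange(0.0, 400.0, 5.0)
        v = np.where(t > 188.0, 0.5, 9.9)
        s = HrvMetricSeries(t, v, v, v, 60.0, 5.0)
        means = hrv.condition_mean(s, "zen", 188.0)
        assert means["lf"] == pytest.approx(0.5)

    def test_control_uses_all_windows(self):
        s = metric_series([1.0, 2.0, 3.0])
        assert hrv.condition_mean(s, "control", 188.0)["lf"] == pytest.approx(2.0)

    def test_no_remaining_windows_rejected(self):
        s = metric_series([1.0, 2.0])
        with pytest.raises(ValueError):
            hrv.condition_mean(s, "zen", 1000.0)
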