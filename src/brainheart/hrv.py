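"""ECG -> R peaks -> corrected IBIs -> time-frequency LF/HF metrics.

The time-frequency estimator is a smoothed pseudo Wigner-Ville
distribution (SPWVD) with independent time (61-sample Hamming) and
frequency (127-sample Hamming lag window) smoothing, evaluated on the
4 Hz cubic-spline-interpolated IBI series with 512 frequency bins over
[0, 0.5] Hz.  Sliding-window LF/HF integrals, the LF/HF ratio, per-
participant min-max normalization, and condition means (with the
paced-breathing exclusion) complete the cardiac branch.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import interpolate, signal as sps

from .datatypes import (
    HF_BAND,
    LF_BAND,
    EcgSignal,
    HrvMetricSeries,
    HrvSpectrogram,
    IbiSeries,
)

__all__ = [
    "bandpass_ecg",
    "detect_r_peaks",
    "correct_ibi",
    "hrv_time_frequency",
    "band_power_series",
    "minmax_normalize",
    "condition_mean",
]


def bandpass_ecg(signal: EcgSignal, low: float = 0.5, high: float = 30.0) -> EcgSignal:
    """Zero-phase 4th-order Butterworth band-pass (default 0.5-30 Hz)."""
    nyq = signal.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band [{low}, {high}] Hz outside (0, {nyq}) Hz")
    sos = sps.butter(4, [low, high], btype="bandpass", fs=signal.sampling_rate, output="sos")
    out = sps.sosfiltfilt(sos, signal.samples)
    return EcgSignal(out, signal.sampling_rate, signal.channel_label)


def detect_r_peaks(signal: EcgSignal) -> np.ndarray:
    """Pan-Tompkins R-peak detection.

    Stages: 5-15 Hz band-pass, five-point derivative, squaring, 150 ms
    moving-window integration, then dual adaptive thresholds with
    search-back and a 200 ms refractory period.  Detected peaks are
    refined to the local maximum of the raw signal.  Returns beat times
    in seconds.
    """
    fs = signal.sampling_rate
    x = signal.samples
    if x.size / fs < 5.0:
        raise ValueError("at least 5 s of ECG needed to initialize thresholds")
    if np.ptp(x) == 0:
        warnings.warn("flat ECG signal: no peaks detected")
        return np.array([])

    sos = sps.butter(3, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, x)
    deriv = np.convolve(filt, np.array([1, 2, 0, -2, -1]) * (fs / 8.0), mode="same")
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        warnings.warn("no candidate peaks above the noise floor")
        return np.array([])

    # adaptive dual thresholds on the MWI peak heights
    spki = float(np.max(mwi[: int(2 * fs)]) / 3.0)
    npki = float(np.mean(mwi[: int(2 * fs)]) / 2.0)
    accepted: list[int] = []
    missed_limit = None  # samples; 1.66 * running RR
    rr_history: list[float] = []

    def threshold1():
        return npki + 0.25 * (spki - npki)

    i = 0
    while i < cand.size:
        idx = cand[i]
        peak = mwi[idx]
        if peak > threshold1():
            if accepted and idx - accepted[-1] < refractory:
                if peak > mwi[accepted[-1]]:
                    accepted[-1] = idx
            else:
                accepted.append(idx)
                spki = 0.125 * peak + 0.875 * spki
                if len(accepted) >= 2:
                    rr_history.append(accepted[-1] - accepted[-2])
                    rr_history = rr_history[-8:]
                    missed_limit = 1.66 * np.mean(rr_history)
        else:
            npki = 0.125 * peak + 0.875 * npki
            # search-back: if we have gone too long without a beat, accept
            # the largest candidate above half threshold in the gap
            if (
                accepted
                and missed_limit is not None
                and idx - accepted[-1] > missed_limit
                and peak > 0.5 * threshold1()
            ):
                accepted.append(idx)
                spki = 0.25 * peak + 0.75 * spki
        i += 1

    if not accepted:
        warnings.warn("no peaks exceeded the adaptive threshold")
        return np.array([])

    # refine to the raw-signal local maximum (R wave) near each MWI peak
    half = int(round(0.100 * fs))
    peaks = []
    for idx in accepted:
        lo, hi = max(0, idx - half), min(x.size, idx + half + 1)
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(peaks)
    # enforce refractory after refinement
    keep = [int(peaks[0])]
    for p in peaks[1:]:
        if p - keep[-1] >= refractory:
            keep.append(int(p))
        elif x[p] > x[keep[-1]]:
            keep[-1] = int(p)
    return np.asarray(keep, dtype=float) / fs


def correct_ibi(beat_times: np.ndarray, max_fraction: float = 0.20) -> IbiSeries:
    """Ectopic/misdetection correction of a beat-time sequence.

    An interval deviating more than 25% from the running median of the
    previous five accepted intervals is treated as an artifact: short
    intervals mark a spurious beat (removed), long intervals mark missed
    beats (restored by cubic-spline interpolation of beat times over the
    beat index).  Intervals outside [0.3, 2.0] s are corrected likewise.
    Emits a warning when more than ``max_fraction`` of beats needed
    correction.
    """
    beats = np.asarray(beat_times, dtype=float)
    if beats.size < 3:
        raise ValueError("at least 3 beats required")

    init = np.median(np.diff(beats)[:5])
    accepted = [beats[0]]
    flags = ["original"]
    gaps: list[tuple[int, int]] = []  # (index in accepted after which to insert, count)
    recent: list[float] = []
    n_removed = 0

    def running_median():
        return np.median(recent[-5:]) if recent else init

    i = 1
    while i < beats.size:
        dt = beats[i] - accepted[-1]
        med = running_median()
        if dt < max(0.75 * med, 0.3):
            # spurious beat: drop it
            n_removed += 1
            i += 1
            continue
        n_missing = int(round(dt / med)) - 1
        if (dt > 1.25 * med or dt > 2.0) and n_missing >= 1:
            # missed beat(s): schedule interpolation
            gaps.append((len(accepted) - 1, n_missing))
            accepted.append(beats[i])
            flags.append("original")
            recent.append(dt / (n_missing + 1))
        else:
            # long-but-not-missed intervals (< 1.5x median) are genuine
            # variability; accept without insertion
            accepted.append(beats[i])
            flags.append("original")
            recent.append(dt)
        i += 1

    accepted = np.asarray(accepted)
    if gaps:
        idx = np.arange(accepted.size, dtype=float)
        spl = interpolate.CubicSpline(idx, accepted)
        new_times = list(accepted)
        new_flags = list(flags)
        insert_at = []
        for k, n_missing in gaps:
            frac = np.arange(1, n_missing + 1) / (n_missing + 1)
            for f in frac:
                insert_at.append((k + f, float(spl(k + f))))
        # merge while preserving order
        merged = sorted(
            [(float(j), t, "original") for j, t in zip(idx, accepted)]
            + [(j, t, "interpolated") for j, t in insert_at]
        )
        times = np.array([t for _, t, _ in merged])
        flags_arr = np.array([fl for _, _, fl in merged])
    else:
        times = accepted
        flags_arr = np.asarray(flags)

    n_corrected = n_removed + int(np.sum(flags_arr == "interpolated"))
    if n_corrected > max_fraction * beats.size:
        warnings.warn(
            f"{n_corrected}/{beats.size} beats corrected (> {max_fraction:.0%}): "
            "recording quality comparable to excluded participants"
        )
    return IbiSeries(times, flags_arr, n_removed=n_removed)


def _spwvd(
    x: np.ndarray,
    fs: float,
    n_freq_bins: int = 512,
    time_window: int = 61,
    lag_window: int = 127,
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed pseudo Wigner-Ville distribution of analytic signal x.

    Returns (freqs, tfr) with ``n_freq_bins`` bins covering [0, fs/8 *
    something) -- concretely bin k maps to ``k * fs / (2 * nfft)`` Hz and
    nfft is chosen so the first ``n_freq_bins`` bins span [0, fs/8].
    For fs = 4 Hz this is [0, 0.5) Hz.  Negative values (residual cross
    terms) are clipped to zero.
    """
    n = x.size
    nfft = 4 * n_freq_bins  # bins cover [0, fs/8) = [0, 0.5) Hz at fs = 4
    lh = lag_window // 2
    lg = time_window // 2
    h = np.hamming(lag_window)
    h = h / h[lh]
    g = np.hamming(time_window)
    g = g / g.sum()

    # R[n_, m] = sum_l g[l] x[n_+m-l] conj(x[n_-m-l]), m = 0..lh
    xp = np.concatenate([np.zeros(lh + lg, complex), x, np.zeros(lh + lg, complex)])
    off = lh + lg
    ns = np.arange(n)
    kernel = np.zeros((n, nfft), dtype=complex)
    for m in range(0, lh + 1):
        acc = np.zeros(n, dtype=complex)
        for li, l in enumerate(range(-lg, lg + 1)):
            acc += g[li] * xp[off + ns + m - l] * np.conj(xp[off + ns - m - l])
        acc *= h[lh + m]
        kernel[:, m] += acc
        if m > 0:
            kernel[:, nfft - m] += np.conj(acc)
    tfr = np.fft.fft(kernel, axis=1).real
    tfr = tfr[:, :n_freq_bins]
    np.clip(tfr, 0, None, out=tfr)
    freqs = np.arange(n_freq_bins) * fs / (2.0 * nfft)
    # scale so that integrating over frequency approximates instantaneous power
    tfr *= 2.0 / fs
    return freqs, tfr


def hrv_time_frequency(
    ibis: IbiSeries,
    interp_rate: float = 4.0,
    n_freq_bins: int = 512,
    time_window: int = 61,
    lag_window: int = 127,
) -> HrvSpectrogram:
    """SPWVD of the interpolated IBI series (power in ms^2/Hz)."""
    if interp_rate < 1.0:
        raise ValueError("interp_rate below 1 Hz cannot resolve the HF band")
    beats = ibis.beat_times
    if beats.size < 2 or beats[-1] - beats[0] < 60.0:
        raise ValueError("at least 60 s of beats required")
    ibi_ms = np.diff(beats) * 1000.0
    t_ibi = beats[1:]
    grid = np.arange(beats[1], beats[-1], 1.0 / interp_rate)
    spl = interpolate.CubicSpline(t_ibi, ibi_ms)
    series = spl(grid)
    series = series - series.mean()
    analytic = sps.hilbert(series)
    freqs, tfr = _spwvd(analytic, interp_rate, n_freq_bins, time_window, lag_window)
    return HrvSpectrogram(grid, freqs, tfr)


def band_integral(spec: HrvSpectrogram, band: tuple[float, float], closed_right: bool = False) -> np.ndarray:
    """Per-time-point rectangle-rule integral of power over a band (ms^2)."""
    lo, hi = band
    if closed_right:
        mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    else:
        mask = (spec.freqs >= lo) & (spec.freqs < hi)
    return spec.power[:, mask].sum(axis=1) * spec.df


def band_power_series(
    spec: HrvSpectrogram, window: float = 60.0, step: float = 5.0
) -> HrvMetricSeries:
    """Sliding-window LF/HF band power and LF/HF ratio (ratio before any scaling)."""
    duration = spec.times[-1] - spec.times[0]
    if window > duration:
        raise ValueError("window longer than spectrogram")
    lf_t = band_integral(spec, LF_BAND, closed_right=False)
    hf_t = band_integral(spec, HF_BAND, closed_right=True)
    t0 = spec.times[0]
    centers = []
    lf, hf = [], []
    c = t0 + window / 2.0
    while c + window / 2.0 <= spec.times[-1] + 1e-9:
        mask = (spec.times >= c - window / 2.0) & (spec.times < c + window / 2.0)
        centers.append(c)
        lf.append(lf_t[mask].mean())
        hf.append(hf_t[mask].mean())
        c += step
    lf = np.asarray(lf)
    hf = np.asarray(hf)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(hf > 0, lf / np.where(hf > 0, hf, 1.0), np.nan)
    return HrvMetricSeries(np.asarray(centers), lf, hf, ratio, window, step)


def minmax_normalize(series_list: list[HrvMetricSeries]) -> list[HrvMetricSeries]:
    """Min-max scale each metric with min/max pooled over all given series.

    The pooling scope is one participant's recordings (both conditions),
    so within-participant condition contrasts survive the scaling.
    """
    out = [s.copy() for s in series_list]
    for metric in HrvMetricSeries.METRICS:
        pooled = np.concatenate([getattr(s, metric) for s in series_list])
        pooled = pooled[np.isfinite(pooled)]
        lo, hi = pooled.min(), pooled.max()
        if hi == lo:
            raise ValueError(f"metric {metric!r} is constant: min-max scaling undefined")
        for s in out:
            setattr(s, metric, (getattr(s, metric) - lo) / (hi - lo))
    for s in out:
        s.normalization = "minmax"
    return out


def condition_mean(
    series: HrvMetricSeries, condition: str, exclusion: float = 188.0
) -> dict[str, float]:
    """Per-metric mean of window centers, excluding the paced-breathing
    epoch (centers <= ``exclusion``) for zen sessions."""
    cutoff = exclusion if condition == "zen" else -np.inf
    mask = series.times > cutoff
    if not mask.any():
        raise ValueError("no windows remain after exclusion")
    out = {}
    for metric in HrvMetricSeries.METRICS:
        vals = getattr(series, metric)[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"no defined {metric} windows remain")
        out[metric] = float(vals.mean())
    return out
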