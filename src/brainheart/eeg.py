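"""EEG denoising, filtering and STFT relative band power.

Processing chain: per-channel Coiflet-3 wavelet denoising (level 6, soft
universal threshold), 50 Hz notch + 1-48 Hz band-pass, optional
linear-phase FIR band extraction, then short-time Fourier relative power
in the four canonical bands (theta/alpha/beta/low-gamma), per electrode,
averaged over configurable electrode groups (default: midline).
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import signal as sps

from .datatypes import (
    CANONICAL_BANDS,
    MIDLINE_CHANNELS,
    BandDefinition,
    BandPowerSeries,
    EegRecording,
    canonical_band_list,
)

__all__ = [
    "wavelet_denoise",
    "notch_bandpass",
    "band_filter",
    "stft_relative_power",
    "group_average",
    "condition_mean_eeg",
    "ELECTRODE_GROUPS",
]

#: configurable electrode groupings; only midline is populated by default
#: (regional groups can be supplied by the caller / pipeline config)
ELECTRODE_GROUPS: dict[str, tuple[str, ...]] = {"midline": MIDLINE_CHANNELS}


def wavelet_denoise(
    rec: EegRecording, wavelet: str = "coif3", level: int = 6
) -> tuple[EegRecording, EegRecording]:
    """Per-channel wavelet artifact suppression; returns (denoised, removed).

    Each channel is decomposed with a multilevel ``coif3`` transform.
    For every detail level a universal threshold sigma_j * sqrt(2 ln N)
    is computed from that level's own median absolute deviation
    (MAD / 0.6745).  Coefficients are clipped at the threshold and the
    *excess* (the soft-thresholded part, i.e. large transient activity
    such as ocular or movement artifacts) is reconstructed as the
    removed-artifact channel, so that ``denoised + removed == input``
    exactly.  Ongoing oscillations whose coefficients sit at or below
    their level's dispersion pass through unchanged.
    """
    n = rec.samples.shape[1]
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
    lvl = min(level, max_level)
    if lvl < 1:
        raise ValueError("too few samples for a single decomposition level")
    den = np.empty_like(rec.samples)
    for i in range(rec.n_channels):
        x = rec.samples[i]
        coeffs = pywt.wavedec(x, wavelet, level=lvl)
        kept = [coeffs[0]]
        for c in coeffs[1:]:
            sigma = np.median(np.abs(c - np.median(c))) / 0.6745
            thr = sigma * np.sqrt(2.0 * np.log(n))
            if thr == 0:
                kept.append(c)  # flat/constant detail: nothing to remove
                continue
            kept.append(np.clip(c, -thr, thr))
        den[i] = pywt.waverec(kept, wavelet)[:n]
    removed = rec.samples - den
    return rec.copy_with(den), rec.copy_with(removed)


def notch_bandpass(
    rec: EegRecording,
    notch_freq: float = 50.0,
    notch_q: float = 30.0,
    band: tuple[float, float] = (1.0, 48.0),
) -> EegRecording:
    """50 Hz notch (Q=30) followed by a zero-phase 1-48 Hz band-pass."""
    fs = rec.sampling_rate
    if fs <= 100:
        raise ValueError("sampling rate must exceed 100 Hz")
    b, a = sps.iirnotch(notch_freq, notch_q, fs=fs)
    x = sps.filtfilt(b, a, rec.samples, axis=1)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x, axis=1)
    return rec.copy_with(x)


def band_filter(rec: EegRecording, band: BandDefinition, transition: float = 2.0) -> EegRecording:
    """Linear-phase Hamming-window FIR band-pass with group-delay compensation.

    The filter order is chosen for a transition width of at most
    ``transition`` Hz (Hamming window: ~3.3 / N normalized width); the
    symmetric kernel is applied with centred convolution so the output
    is delay-free.
    """
    fs = rec.sampling_rate
    nyq = fs / 2.0
    if not (0 < band.low < band.high < nyq):
        raise ValueError(f"band [{band.low}, {band.high}] outside (0, {nyq}) Hz")
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps |= 1  # odd for a symmetric (type-I) linear-phase kernel
    taps = sps.firwin(numtaps, [band.low, band.high], pass_zero=False, window="hamming", fs=fs)
    out = np.empty_like(rec.samples)
    for i in range(rec.n_channels):
        out[i] = sps.fftconvolve(rec.samples[i], taps, mode="same")
    return rec.copy_with(out)


def stft_relative_power(
    rec: EegRecording,
    bands: list[BandDefinition] | None = None,
    window: float = 1.0,
    overlap: float = 0.5,
    extra_bands: list[BandDefinition] | None = None,
) -> dict[str, BandPowerSeries]:
    """Per-channel relative band power from a Hann-tapered STFT.

    Band power per frame is the sum of squared STFT magnitudes over the
    band's bins; relative power divides by the summed power of the four
    canonical bands.  ``extra_bands`` (e.g. high-alpha 10-13 Hz) are
    reported with the same canonical-sum denominator.  All-zero frames
    are flagged by NaN.
    """
    if window < 1.0:
        raise ValueError("window must be at least 1 s (4 Hz resolvable)")
    if bands is None:
        bands = canonical_band_list()
    canon = set(CANONICAL_BANDS)
    if {b.name for b in bands} != canon:
        raise ValueError(f"bands must be the canonical set {sorted(canon)}")
    extra_bands = extra_bands or []
    fs = rec.sampling_rate
    nper = int(round(window * fs))
    hop = int(round(nper * (1.0 - overlap)))
    n = rec.samples.shape[1]
    n_frames = (n - nper) // hop + 1
    if n_frames < 1:
        raise ValueError("recording shorter than one STFT window")
    taper = np.hanning(nper)
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    all_bands = list(bands) + list(extra_bands)
    masks = [(freqs >= b.low) & (freqs < b.high) for b in all_bands]
    canon_idx = [j for j, b in enumerate(all_bands) if b.name in canon]

    starts = np.arange(n_frames) * hop
    centers = (starts + nper / 2.0) / fs
    out: dict[str, BandPowerSeries] = {}
    for ci, ch in enumerate(rec.channel_labels):
        x = rec.samples[ci]
        frames = np.lib.stride_tricks.sliding_window_view(x, nper)[::hop][:n_frames]
        spec = np.abs(np.fft.rfft(frames * taper, axis=1)) ** 2
        bp = np.stack([spec[:, mk].sum(axis=1) for mk in masks], axis=1)
        total = bp[:, canon_idx].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(total[:, None] > 0, bp / np.where(total[:, None] > 0, total[:, None], 1.0), np.nan)
        out[ch] = BandPowerSeries(
            centers, rel, tuple(b.name for b in all_bands), electrode_group=ch,
            constituent_channels=(ch,),
        )
    return out


def group_average(
    series: dict[str, BandPowerSeries], group: str | tuple[str, ...] = "midline"
) -> BandPowerSeries:
    """Unweighted mean of per-channel relative powers over an electrode group."""
    if isinstance(group, str):
        label = group
        channels = ELECTRODE_GROUPS.get(group)
        if channels is None:
            raise KeyError(f"unknown electrode group {group!r}")
    else:
        label = "+".join(group)
        channels = tuple(group)
    missing = [c for c in channels if c not in series]
    if missing:
        raise ValueError(f"missing channel(s) for group {label!r}: {missing}")
    first = series[channels[0]]
    stacked = np.stack([series[c].values for c in channels])
    return BandPowerSeries(
        first.times, stacked.mean(axis=0), first.band_names, label, channels
    )


def condition_mean_eeg(
    series: BandPowerSeries, condition: str, exclusion: float = 188.0
) -> dict[str, float]:
    """Per-band mean of frame centers; zen excludes the paced-breathing epoch."""
    cutoff = exclusion if condition == "zen" else -np.inf
    mask = series.times > cutoff
    if not mask.any():
        raise ValueError("no frames remain after exclusion")
    out = {}
    for name in series.band_names:
        vals = series.band(name)[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"no defined frames for band {name!r}")
        out[name] = float(vals.mean())
    return out
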