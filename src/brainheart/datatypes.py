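"""Shared physiological data containers.

These are thin, validated dataclasses; heavy numerics live in the stage
modules (:mod:`brainheart.hrv`, :mod:`brainheart.eeg`,
:mod:`brainheart.coupling`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Midline electrodes of the 10-10 montage used for the primary analyses.
MIDLINE_CHANNELS = ("AFz", "Fz", "Cz", "CPz", "Pz", "POz", "Oz", "Iz")

#: Canonical EEG bands (Hz, half-open intervals) used for relative power.
CANONICAL_BANDS = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "low_gamma": (30.0, 46.0),
}

#: Optional extra band referenced by regional analyses.
HIGH_ALPHA_BAND = ("high_alpha", (10.0, 13.0))

#: HRV spectral bands (Hz). LF is half-open, HF closed on the right.
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not (0 < self.low < self.high):
            raise ValueError(f"band {self.name!r}: need 0 < low < high, got [{self.low}, {self.high})")


def canonical_band_list() -> list[BandDefinition]:
    return [BandDefinition(n, lo, hi) for n, (lo, hi) in CANONICAL_BANDS.items()]


@dataclass
class EcgSignal:
    """Single-channel ECG trace in microvolts."""

    samples: np.ndarray
    sampling_rate: float
    channel_label: str = "ECG"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass
class EegRecording:
    """Multichannel EEG, channels x time, in microvolts."""

    samples: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...]
    markers: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} rows but {len(self.channel_labels)} channel labels"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        dur = self.duration
        for label, t in self.markers:
            if not (0 <= t <= dur):
                raise ValueError(f"marker {label!r} at {t} s outside recording of {dur} s")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None
        return self.samples[idx]

    def copy_with(self, samples: np.ndarray) -> "EegRecording":
        return EegRecording(samples, self.sampling_rate, self.channel_labels, list(self.markers))


@dataclass
class IbiSeries:
    """Beat times (s) and the inter-beat intervals they imply.

    ``correction_flags`` holds one flag per beat: ``"original"`` or
    ``"interpolated"``; removed beats are not carried (their removal is
    recorded in ``n_removed``).
    """

    beat_times: np.ndarray
    correction_flags: Optional[np.ndarray] = None
    n_removed: int = 0

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.size and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if self.correction_flags is None:
            self.correction_flags = np.array(["original"] * self.beat_times.size)
        else:
            self.correction_flags = np.asarray(self.correction_flags)
            if self.correction_flags.size != self.beat_times.size:
                raise ValueError("one correction flag per beat required")

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.beat_times)

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)


@dataclass
class HrvSpectrogram:
    """Time x frequency power surface of the RR modulation (ms^2/Hz)."""

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (self.times.size, self.freqs.size):
            raise ValueError("power must be (n_times, n_freqs)")
        if np.any(self.power < 0):
            raise ValueError("spectrogram power must be nonnegative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class HrvMetricSeries:
    """Sliding-window LF/HF band power and their ratio.

    ``lf_hf`` is NaN in windows where the HF integral vanished (flagged
    undefined; such windows are excluded from averages).
    """

    times: np.ndarray
    lf: np.ndarray
    hf: np.ndarray
    lf_hf: np.ndarray
    window: float
    step: float
    normalization: str = "raw"

    METRICS = ("lf", "hf", "lf_hf")

    def __post_init__(self):
        for name in ("times", "lf", "hf", "lf_hf"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.times.size
        if not all(getattr(self, m).size == n for m in self.METRICS):
            raise ValueError("metric arrays must match times")

    def copy(self) -> "HrvMetricSeries":
        return HrvMetricSeries(
            self.times.copy(), self.lf.copy(), self.hf.copy(), self.lf_hf.copy(),
            self.window, self.step, self.normalization,
        )


@dataclass
class BandPowerSeries:
    """Per-frame relative EEG band power for one channel or channel group."""

    times: np.ndarray
    values: np.ndarray  # frames x bands
    band_names: tuple[str, ...]
    electrode_group: str
    constituent_channels: tuple[str, ...]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.band_names = tuple(self.band_names)
        self.constituent_channels = tuple(self.constituent_channels)
        if self.values.shape != (self.times.size, len(self.band_names)):
            raise ValueError("values must be (n_frames, n_bands)")

    def band(self, name: str) -> np.ndarray:
        try:
            j = self.band_names.index(name)
        except ValueError:
            raise KeyError(f"band {name!r} not present") from None
        return self.values[:, j]


@dataclass
class CouplingSeries:
    """Time courses of the four directional coupling coefficients."""

    times: np.ndarray
    b2hf: np.ndarray
    b2lf: np.ndarray
    hf2b: np.ndarray
    lf2b: np.ndarray
    quality_flags: Optional[np.ndarray] = None

    COEFFICIENTS = ("b2hf", "b2lf", "hf2b", "lf2b")

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        for c in self.COEFFICIENTS:
            setattr(self, c, np.asarray(getattr(self, c), dtype=float))
            if getattr(self, c).size != self.times.size:
                raise ValueError(f"{c} must match times")
        if self.quality_flags is None:
            self.quality_flags = np.array(["ok"] * self.times.size)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class SessionRecord:
    """One recording session (zen or control) of one participant."""

    condition: str
    ecg: EcgSignal
    eeg: EegRecording
    breathing_epoch_end: Optional[float] = None
    ground_truth: Optional[object] = None  # SdgSimConfig when synthetic
    ground_truth_aux: Optional[dict] = None

    def __post_init__(self):
        if self.condition not in ("zen", "control"):
            raise ValueError("condition must be 'zen' or 'control'")
        if self.condition == "zen" and self.breathing_epoch_end is None:
            raise ValueError("zen sessions must carry breathing_epoch_end")
        if abs(self.ecg.duration - self.eeg.duration) > 1.0 / min(
            self.ecg.sampling_rate, self.eeg.sampling_rate
        ):
            raise ValueError("ECG and EEG durations must agree within one sample")


@dataclass
class ParticipantRecord:
    """STAI triplet plus the two condition sessions of one participant."""

    id: str
    stai_baseline: int
    stai_before: int
    stai_after: int
    sessions: dict  # {"zen": SessionRecord, "control": SessionRecord}
    condition_order: str = "zen_first"
    group: Optional[str] = None

    def __post_init__(self):
        for name in ("stai_baseline", "stai_before", "stai_after"):
            v = getattr(self, name)
            if not (20 <= v <= 80):
                raise ValueError(f"{name}={v} outside STAI-Y1 range [20, 80]")
        if set(self.sessions) != {"zen", "control"}:
            raise ValueError("both a zen and a control session are required")
        if self.condition_order not in ("zen_first", "control_first"):
            raise ValueError("condition_order must be zen_first or control_first")
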