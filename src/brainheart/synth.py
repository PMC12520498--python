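"""Synthetic coupled EEG / heartbeat generator.

The heartbeat side follows the integral pulse frequency modulation (IPFM)
model: with instantaneous modulation m(t), a beat is emitted each time

    Phi(t) = integral_0^t (1 + m(s)) * HR/60 ds

crosses an integer.  m(t) is a sum of LF and HF sinusoidal oscillators
(optionally a paced-respiration sinusoid during the breathing epoch) plus
white noise; the oscillator amplitudes may be slowly modulated and, in
coupled scenarios, driven by the lagged standardized EEG beta envelope
(brain->heart) -- or the beta envelope may be driven by the lagged
standardized oscillator power (heart->brain).

The EEG side is a 1/f background plus a 10 Hz alpha rhythm and a 20 Hz
beta carrier whose envelope is a rectified, smoothed Ornstein-Uhlenbeck
process shared across midline channels.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import signal as sps

from .datatypes import (
    MIDLINE_CHANNELS,
    EcgSignal,
    EegRecording,
    IbiSeries,
    ParticipantRecord,
    SessionRecord,
)

#: internal integration grid for the IPFM integral (Hz)
_IPFM_GRID_HZ = 200.0


@dataclass(frozen=True)
class OscillatorSpec:
    """One sinusoidal rate oscillator: modulation depth at a centre frequency."""

    center_freq: float  # Hz
    amplitude: float  # dimensionless in [0, 1)
    phase: float = 0.0  # rad

    def __post_init__(self):
        if self.center_freq <= 0:
            raise ValueError("center_freq must be positive")
        if not (0 <= self.amplitude < 1):
            raise ValueError("amplitude must lie in [0, 1): IPFM rate must stay positive")


@dataclass(frozen=True)
class BreathingEpoch:
    """Paced-breathing epoch: a respiratory sinusoid at 1/(inspiration+expiration)."""

    duration: float = 188.0  # s
    inspiration: float = 4.0  # s
    expiration: float = 6.0  # s
    amplitude: float = 0.1  # modulation depth of the respiratory oscillator

    @property
    def frequency(self) -> float:
        return 1.0 / (self.inspiration + self.expiration)


@dataclass(frozen=True)
class SdgSimConfig:
    """Parameters of one simulated session.

    Exactly one of the gain families (brain->heart ``b2h_gain_*`` /
    heart->brain ``h2b_gain_*``) may be nonzero; this keeps simulated
    scenarios unidirectional so directionality estimates have an
    unambiguous ground truth.
    """

    mean_hr: float = 70.0  # beats/min
    lf_osc: OscillatorSpec = OscillatorSpec(0.1, 0.05)
    hf_osc: OscillatorSpec = OscillatorSpec(0.25, 0.05)
    breathing_epoch: Optional[BreathingEpoch] = None
    b2h_gain_lf: float = 0.0
    b2h_gain_hf: float = 0.0
    h2b_gain_lf: float = 0.0
    h2b_gain_hf: float = 0.0
    coupling_delay: float = 2.0  # s
    amplitude_jitter: float = 0.3  # slow stochastic modulation of oscillator amplitudes
    noise_sd: float = 0.01  # white noise in m(t)
    eeg_noise_rms: float = 10.0  # uV, 1/f background
    alpha_amplitude: float = 5.0  # uV at 10 Hz
    beta_amplitude: float = 3.0  # uV carrier scale at 20 Hz
    seed: int = 0

    def __post_init__(self):
        b2h = abs(self.b2h_gain_lf) + abs(self.b2h_gain_hf)
        h2b = abs(self.h2b_gain_lf) + abs(self.h2b_gain_hf)
        if b2h > 0 and h2b > 0:
            raise ValueError("only one gain family (b2h or h2b) may be nonzero")
        for g in (self.b2h_gain_lf, self.b2h_gain_hf, self.h2b_gain_lf, self.h2b_gain_hf):
            if not np.isfinite(g):
                raise ValueError("gains must be finite")

    def validate_depth(self) -> None:
        total = self.lf_osc.amplitude + self.hf_osc.amplitude + 3 * self.noise_sd
        if self.breathing_epoch is not None:
            total += self.breathing_epoch.amplitude
        if total >= 1:
            raise ValueError(
                f"total modulation depth {total:.3f} >= 1: instantaneous rate could go negative"
            )


def _ou_envelope(n: int, dt: float, rng: np.random.Generator, tau: float = 2.0,
                 smooth: float = 2.0) -> np.ndarray:
    """Rectified, smoothed Ornstein-Uhlenbeck process (positive, stationary)."""
    a = np.exp(-dt / tau)
    s = np.sqrt(1 - a * a)
    x0 = rng.standard_normal()
    innov = rng.standard_normal(n - 1)
    rest, _ = sps.lfilter([s], [1.0, -a], innov, zi=[a * x0])
    env = np.abs(np.concatenate([[x0], rest]))
    k = max(3, int(round(smooth / dt)) | 1)
    kernel = np.hanning(k)
    kernel /= kernel.sum()
    return np.convolve(env, kernel, mode="same")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _ipfm_beats(t: np.ndarray, m: np.ndarray, mean_hr: float) -> np.ndarray:
    """Integrate the modulated rate and return integer-crossing times."""
    rate = (1.0 + m) * mean_hr / 60.0
    if np.min(rate) <= 0:
        raise ValueError("modulation depth >= 1: negative instantaneous rate")
    dt = t[1] - t[0]
    phi = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) * 0.5 * dt)])
    n_beats = int(np.floor(phi[-1]))
    targets = np.arange(1, n_beats + 1, dtype=float)
    idx = np.searchsorted(phi, targets)
    idx = np.clip(idx, 1, phi.size - 1)
    frac = (targets - phi[idx - 1]) / (phi[idx] - phi[idx - 1])
    times = t[idx - 1] + frac * dt
    return np.concatenate([[0.0], times])


def _modulation(
    config: SdgSimConfig,
    t: np.ndarray,
    rng: np.random.Generator,
    beta_envelope: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, dict]:
    """Build m(t) on grid t; returns (m, aux with amplitude/power series)."""
    dt = t[1] - t[0]
    delay_n = int(round(config.coupling_delay / dt))

    def lagged(x):
        if delay_n == 0:
            return x
        out = np.empty_like(x)
        out[delay_n:] = x[:-delay_n]
        out[:delay_n] = x[0]
        return out

    a_lf = np.full(t.size, config.lf_osc.amplitude)
    a_hf = np.full(t.size, config.hf_osc.amplitude)
    if config.amplitude_jitter > 0:
        a_lf = a_lf * (1 + config.amplitude_jitter * _standardize(_ou_envelope(t.size, dt, rng, tau=10.0, smooth=5.0)))
        a_hf = a_hf * (1 + config.amplitude_jitter * _standardize(_ou_envelope(t.size, dt, rng, tau=10.0, smooth=5.0)))
    if beta_envelope is not None and (config.b2h_gain_lf or config.b2h_gain_hf):
        # standardized envelope clipped at +-1.5 to bound modulation depth
        e = lagged(np.clip(_standardize(beta_envelope), -1.5, 1.5))
        a_lf = a_lf * (1 + config.b2h_gain_lf * e)
        a_hf = a_hf * (1 + config.b2h_gain_hf * e)
    a_lf = np.clip(a_lf, 0, None)
    a_hf = np.clip(a_hf, 0, None)

    m = a_lf * np.sin(2 * np.pi * config.lf_osc.center_freq * t + config.lf_osc.phase)
    m = m + a_hf * np.sin(2 * np.pi * config.hf_osc.center_freq * t + config.hf_osc.phase)
    if config.breathing_epoch is not None:
        be = config.breathing_epoch
        mask = t < be.duration
        m = m + mask * be.amplitude * np.sin(2 * np.pi * be.frequency * t)
    if config.noise_sd > 0:
        m = m + config.noise_sd * rng.standard_normal(t.size)
    m = np.clip(m, -0.95, 0.95)
    aux = {"t": t, "a_lf": a_lf, "a_hf": a_hf}
    return m, aux


def generate_rr_ipfm(config: SdgSimConfig, duration: float) -> IbiSeries:
    """Generate beat times on [0, duration] from the IPFM model."""
    config.validate_depth()
    rng = np.random.default_rng(config.seed)
    t = np.arange(0, duration + 1 / _IPFM_GRID_HZ, 1 / _IPFM_GRID_HZ)
    m, _ = _modulation(config, t, rng)
    beats = _ipfm_beats(t, m, config.mean_hr)
    return IbiSeries(beats[beats <= duration])


def generate_ecg_from_beats(
    beats: IbiSeries,
    sampling_rate: float = 1000.0,
    qrs_amplitude: float = 1000.0,
    duration: Optional[float] = None,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> EcgSignal:
    """Place a QRS-like template (R peak with small Q/S lobes) at each beat time."""
    if sampling_rate < 100:
        raise ValueError("sampling_rate below 100 Hz cannot represent a QRS template")
    if duration is None:
        duration = float(beats.beat_times[-1]) + 1.0 if beats.n_beats else 1.0
    n = int(round(duration * sampling_rate))
    x = np.zeros(n)
    t = np.arange(n) / sampling_rate
    # R wave: narrow Gaussian; Q and S: small negative lobes either side
    for center in beats.beat_times:
        lo = max(0, int((center - 0.1) * sampling_rate))
        hi = min(n, int((center + 0.1) * sampling_rate) + 1)
        tt = t[lo:hi] - center
        x[lo:hi] += qrs_amplitude * (
            np.exp(-0.5 * (tt / 0.008) ** 2)
            - 0.15 * np.exp(-0.5 * ((tt + 0.025) / 0.010) ** 2)
            - 0.20 * np.exp(-0.5 * ((tt - 0.025) / 0.010) ** 2)
        )
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        x = x + noise_sd * rng.standard_normal(n)
    return EcgSignal(x, sampling_rate)


def _pink_noise(n: int, rng: np.random.Generator, exponent: float = 1.0) -> np.ndarray:
    """FFT-shaped 1/f^exponent noise, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec = spec / f ** (exponent / 2.0)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def generate_coupled_session(
    config: SdgSimConfig,
    condition: str,
    duration: float = 1200.0,
    ecg_fs: float = 1000.0,
    eeg_fs: float = 1000.0,
    channels: tuple[str, ...] = MIDLINE_CHANNELS,
) -> SessionRecord:
    """Generate one session with tunable, directional EEG-beta <-> HRV coupling.

    Zen sessions carry the paced-breathing epoch (marker at its end);
    control sessions do not.  The embedded ``ground_truth`` is the config;
    ``ground_truth_aux`` holds the realized beta envelope and oscillator
    amplitude series on the internal grid for recovery tests.
    """
    cfg = config
    if condition == "zen" and cfg.breathing_epoch is None:
        cfg = replace(cfg, breathing_epoch=BreathingEpoch())
    elif condition == "control" and cfg.breathing_epoch is not None:
        cfg = replace(cfg, breathing_epoch=None)
    cfg.validate_depth()
    rng = np.random.default_rng(cfg.seed)
    r_env, r_mod, r_eeg, r_ecg = rng.spawn(4)

    t = np.arange(0, duration + 1 / _IPFM_GRID_HZ, 1 / _IPFM_GRID_HZ)
    dt = t[1] - t[0]
    envelope = _ou_envelope(t.size, dt, r_env)

    h2b = cfg.h2b_gain_lf or cfg.h2b_gain_hf
    if h2b:
        # heart->brain: build the heart first, then drive the envelope
        m, aux = _modulation(cfg, t, r_mod)
        delay_n = int(round(cfg.coupling_delay / dt))
        p_lf = _standardize(np.roll(aux["a_lf"] ** 2, delay_n))
        p_hf = _standardize(np.roll(aux["a_hf"] ** 2, delay_n))
        drive = cfg.h2b_gain_lf * p_lf + cfg.h2b_gain_hf * p_hf
        mean_before = envelope.mean()
        envelope = np.clip(envelope * (1 + drive), 0, None)
        # renormalize so the drive shapes the envelope's dynamics without
        # changing its mean level (beta power stays comparable across scenarios)
        if envelope.mean() > 0:
            envelope *= mean_before / envelope.mean()
    else:
        m, aux = _modulation(cfg, t, r_mod, beta_envelope=envelope)
    beats = _ipfm_beats(t, m, cfg.mean_hr)
    beats = beats[beats <= duration]

    ecg = generate_ecg_from_beats(
        IbiSeries(beats), ecg_fs, duration=duration, noise_sd=5.0, rng=r_ecg
    )

    n_eeg = int(round(duration * eeg_fs))
    te = np.arange(n_eeg) / eeg_fs
    env_eeg = np.interp(te, t, envelope)
    eeg = np.empty((len(channels), n_eeg))
    for i in range(len(channels)):
        bg = cfg.eeg_noise_rms * _pink_noise(n_eeg, r_eeg)
        alpha = cfg.alpha_amplitude * np.sin(2 * np.pi * 10.0 * te + r_eeg.uniform(0, 2 * np.pi))
        beta = cfg.beta_amplitude * env_eeg * np.sin(2 * np.pi * 20.0 * te + r_eeg.uniform(0, 2 * np.pi))
        eeg[i] = bg + alpha + beta
    markers = []
    breathing_end = None
    if condition == "zen":
        breathing_end = cfg.breathing_epoch.duration
        markers.append(("breathing_end", float(breathing_end)))
    rec = EegRecording(eeg, eeg_fs, channels, markers)
    return SessionRecord(
        condition=condition,
        ecg=ecg,
        eeg=rec,
        breathing_epoch_end=breathing_end,
        ground_truth=cfg,
        ground_truth_aux={"t": t, "beta_envelope": envelope, "a_lf": aux["a_lf"],
                          "a_hf": aux["a_hf"], "beat_times": beats},
    )


@dataclass(frozen=True)
class CohortSpec:
    """Session parameters shared by all participants of a synthetic cohort.

    Responders: control sessions have ascending heart->brain coupling;
    zen sessions have descending brain->heart coupling plus elevated LF/HF
    oscillator amplitudes and beta power.  Non-responders: no coupling in
    either condition and only the LF amplitude elevated in zen.  The STAI
    decrement of responders scales with the realized LF/HF amplitude-power
    ratio of their zen session.
    """

    duration: float = 1200.0
    ecg_fs: float = 1000.0
    eeg_fs: float = 1000.0
    channels: tuple[str, ...] = MIDLINE_CHANNELS
    lf_amp_control: float = 0.05
    hf_amp_control: float = 0.045
    lf_amp_zen: float = 0.11
    hf_amp_zen_responder: float = 0.06
    beta_amp_control: float = 3.0
    beta_amp_zen_responder: float = 5.0
    b2h_gain: float = 1.2
    h2b_gain: float = 1.0
    stai_slope: float = 3.0  # k: decrement = round(k * realized LF/HF + eps)


def _session_config(base_seed: int, lf_amp: float, hf_amp: float, beta_amp: float,
                    b2h: float = 0.0, h2b: float = 0.0) -> SdgSimConfig:
    return SdgSimConfig(
        lf_osc=OscillatorSpec(0.1, lf_amp),
        hf_osc=OscillatorSpec(0.25, hf_amp),
        b2h_gain_lf=b2h,
        b2h_gain_hf=b2h,
        h2b_gain_lf=h2b,
        h2b_gain_hf=h2b,
        beta_amplitude=beta_amp,
        seed=base_seed,
    )


def generate_cohort(
    n_responders: int,
    n_nonresponders: int,
    seed: int,
    spec: CohortSpec = CohortSpec(),
) -> list[ParticipantRecord]:
    """Synthetic cohort with known responder structure (see :class:`CohortSpec`)."""
    if n_responders < 0 or n_nonresponders < 0:
        raise ValueError("counts must be nonnegative")
    rng = np.random.default_rng(seed)
    records = []
    total = n_responders + n_nonresponders
    for i in range(total):
        responder = i < n_responders
        pid = f"P{i + 1:03d}"
        s_zen = int(rng.integers(0, 2**31 - 1))
        s_ctl = int(rng.integers(0, 2**31 - 1))
        if responder:
            cfg_zen = _session_config(
                s_zen, spec.lf_amp_zen, spec.hf_amp_zen_responder,
                spec.beta_amp_zen_responder, b2h=spec.b2h_gain,
            )
            cfg_ctl = _session_config(
                s_ctl, spec.lf_amp_control, spec.hf_amp_control,
                spec.beta_amp_control, h2b=spec.h2b_gain,
            )
        else:
            cfg_zen = _session_config(
                s_zen, spec.lf_amp_zen, spec.hf_amp_control, spec.beta_amp_control
            )
            cfg_ctl = _session_config(
                s_ctl, spec.lf_amp_control, spec.hf_amp_control, spec.beta_amp_control
            )
        zen = generate_coupled_session(
            cfg_zen, "zen", spec.duration, spec.ecg_fs, spec.eeg_fs, spec.channels
        )
        control = generate_coupled_session(
            cfg_ctl, "control", spec.duration, spec.ecg_fs, spec.eeg_fs, spec.channels
        )
        baseline = int(rng.integers(30, 51))
        before = int(np.clip(baseline + rng.integers(-3, 4), 21, 79))
        if responder:
            aux = zen.ground_truth_aux
            lfhf = float(np.mean(aux["a_lf"] ** 2) / np.mean(aux["a_hf"] ** 2))
            eps = abs(rng.standard_normal())
            dec = max(1, int(round(spec.stai_slope * lfhf + eps)))
            after = max(20, before - dec)
            if after >= before:  # before was already at floor
                after = before - 1
        else:
            after = min(80, before + int(rng.integers(0, 3)))
        order = "zen_first" if rng.integers(0, 2) else "control_first"
        records.append(
            ParticipantRecord(
                id=pid,
                stai_baseline=baseline,
                stai_before=before,
                stai_after=after,
                sessions={"zen": zen, "control": control},
                condition_order=order,
                group="responsive" if responder else "unresponsive",
            )
        )
    return records
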