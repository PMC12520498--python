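import numpy as np
import pytest

from brainheart.synth import OscillatorSpec, SdgSimConfig, generate_coupled_session


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_session(seed=1, duration=300.0, b2h=0.0, h2b=0.0, condition="control",
                 lf_amp=0.05, hf_amp=0.05, beta_amp=3.0, ecg_fs=250.0, eeg_fs=128.0):
    cfg = SdgSimConfig(
        lf_osc=OscillatorSpec(0.1, lf_amp),
        hf_osc=OscillatorSpec(0.25, hf_amp),
        b2h_gain_lf=b2h, b2h_gain_hf=b2h,
        h2b_gain_lf=h2b, h2b_gain_hf=h2b,
        beta_amplitude=beta_amp,
        seed=seed,
    )
    return generate_coupled_session(cfg, condition, duration, ecg_fs, eeg_fs)


def process_session_fast(sess, coupling_window=15.0, coupling_step=1.0):
    """ECG+EEG -> (aligned t, beta, lf, hf) without wavelet denoising."""
    from brainheart import eeg as eegmod
    from brainheart import hrv as hrvmod
    from brainheart.coupling import align_series

    peaks = hrvmod.detect_r_peaks(hrvmod.bandpass_ecg(sess.ecg))
    ibis = hrvmod.correct_ibi(peaks)
    spec = hrvmod.hrv_time_frequency(ibis)
    hm = hrvmod.band_power_series(spec, coupling_window, coupling_step)
    rec = eegmod.notch_bandpass(sess.eeg)
    beta = eegmod.group_average(eegmod.stft_relative_power(rec), "midline")
    return align_series(beta, hm)
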