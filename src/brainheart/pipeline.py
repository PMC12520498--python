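"""End-to-end pipelines: configuration, per-participant processing,
cohort assembly and the run manifest.

``run_full_pipeline`` takes a cohort (synthetic via
:func:`brainheart.synth.generate_cohort` or loaded from files) through
ECG -> HRV metrics, EEG -> relative band power, coupling estimation and
cohort inference, with per-participant fault isolation: a failing
participant is logged and excluded, mirroring attrition bookkeeping in
real studies.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import eeg as eegmod
from . import hrv as hrvmod
from .coupling import BrainHeartModel, CouplingConfig, condition_mean_coupling
from .datatypes import MIDLINE_CHANNELS
from .stats import AnxietyStudy

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "ParticipantMetrics", "PipelineResult",
           "process_session", "process_participant", "run_full_pipeline"]


@dataclass
class PipelineConfig:
    """Every stage parameter, defaulting to the study's stated values."""

    ecg_band: tuple[float, float] = (0.5, 30.0)
    eeg_notch: float = 50.0
    eeg_band: tuple[float, float] = (1.0, 48.0)
    denoise_wavelet: str = "coif3"
    denoise_level: int = 6
    apply_denoise: bool = True
    stft_window: float = 1.0
    stft_overlap: float = 0.5
    hrv_interp_rate: float = 4.0
    hrv_window: float = 60.0
    hrv_step: float = 5.0
    coupling_window: float = 15.0
    coupling_step: float = 1.0
    exclusion_s: float = 188.0
    electrode_group: str = "midline"
    electrode_groups: dict = field(
        default_factory=lambda: {"midline": list(MIDLINE_CHANNELS)}
    )
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    average_interpolated_coupling: bool = True
    seed: int = 0

    def to_yaml(self, path) -> Path:
        path = Path(path)
        d = asdict(self)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "coupling" in d and isinstance(d["coupling"], dict):
            d["coupling"] = CouplingConfig(**d["coupling"])
        for key in ("ecg_band", "eeg_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record: config hash, version, seeds, per-participant log."""

    config_hash: str
    version: str
    seed: int
    log: list = field(default_factory=list)

    def record(self, participant: str, event: str) -> None:
        self.log.append({"participant": participant, "event": event})
        logger.info("%s: %s", participant, event)

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))
        return path


@dataclass
class ParticipantMetrics:
    participant: str
    condition: str
    metrics: dict  # lf/hf/lf_hf/alpha/beta (+ coupling coefficients)
    hrv_series: object = None
    beta_series: object = None
    coupling: object = None  # BrainHeartResults


def process_session(session, config: PipelineConfig):
    """One session -> (hrv metric series [raw], beta band-power series)."""
    ecg = hrvmod.bandpass_ecg(session.ecg, *config.ecg_band)
    peaks = hrvmod.detect_r_peaks(ecg)
    ibis = hrvmod.correct_ibi(peaks)
    spec = hrvmod.hrv_time_frequency(ibis, config.hrv_interp_rate)
    hrv_win = hrvmod.band_power_series(spec, config.hrv_window, config.hrv_step)
    hrv_coupling = hrvmod.band_power_series(spec, config.coupling_window, config.coupling_step)

    rec = session.eeg
    if config.apply_denoise:
        rec, _ = eegmod.wavelet_denoise(rec, config.denoise_wavelet, config.denoise_level)
    rec = eegmod.notch_bandpass(rec, config.eeg_notch, band=config.eeg_band)
    per_channel = eegmod.stft_relative_power(rec, window=config.stft_window,
                                             overlap=config.stft_overlap)
    group = config.electrode_groups.get(config.electrode_group)
    beta = eegmod.group_average(per_channel, tuple(group) if group else config.electrode_group)
    return hrv_win, hrv_coupling, beta


def process_participant(record, config: PipelineConfig) -> list[ParticipantMetrics]:
    """Both sessions of one participant -> per-condition metric rows.

    HRV metrics are min-max normalized with min/max pooled over the two
    conditions before condition means are taken.
    """
    per_cond = {}
    for cond in ("zen", "control"):
        per_cond[cond] = process_session(record.sessions[cond], config)

    hrv_norm = hrvmod.minmax_normalize([per_cond["zen"][0], per_cond["control"][0]])
    out = []
    for cond, hrv_n in zip(("zen", "control"), hrv_norm):
        _, hrv_coup, beta = per_cond[cond]
        metrics = hrvmod.condition_mean(hrv_n, cond, config.exclusion_s)
        eeg_means = eegmod.condition_mean_eeg(beta, cond, config.exclusion_s)
        metrics["alpha"] = eeg_means["alpha"]
        metrics["beta"] = eeg_means["beta"]
        model = BrainHeartModel(beta, hrv_coup, config.coupling)
        res = model.fit()
        eeg_times = beta.times if config.average_interpolated_coupling else None
        cmeans = res.condition_mean(cond, config.exclusion_s, eeg_times)
        metrics.update(cmeans)
        out.append(ParticipantMetrics(record.id, cond, metrics,
                                      hrv_series=hrv_n, beta_series=beta, coupling=res))
    return out


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    study: object  # AnxietyStudyResults or None
    manifest: RunManifest
    per_participant: list

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(outdir / "metrics.csv", index=False, float_format="%.8f")
        if self.study is not None:
            self.study.comparisons_frame().to_csv(
                outdir / "comparisons.csv", index=False, float_format="%.8f"
            )
            (outdir / "report.md").write_text(self.study.summary() + "\n")
        self.manifest.to_json(outdir / "manifest.json")


def run_full_pipeline(cohort: list, config: Optional[PipelineConfig] = None,
                      fit_study: bool = True) -> PipelineResult:
    """Cohort of :class:`~brainheart.datatypes.ParticipantRecord` -> result bundle."""
    config = config or PipelineConfig()
    manifest = RunManifest(config.config_hash(), _version, config.seed)
    rows = []
    per_participant = []
    for record in cohort:
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                pms = process_participant(record, config)
            for w in caught:
                manifest.record(record.id, f"warning: {w.message}")
        except Exception as exc:  # fault isolation per participant
            manifest.record(record.id, f"excluded: {exc}")
            continue
        per_participant.extend(pms)
        for pm in pms:
            row = {
                "participant": record.id,
                "condition": pm.condition,
                "stai_baseline": record.stai_baseline,
                "stai_before": record.stai_before,
                "stai_after": record.stai_after,
                "condition_order": record.condition_order,
            }
            row.update(pm.metrics)
            rows.append(row)
        manifest.record(record.id, "processed")
    metrics = pd.DataFrame(rows)
    study = None
    if fit_study and len(metrics) and metrics["participant"].nunique() >= 5:
        study = AnxietyStudy(metrics).fit()
    return PipelineResult(metrics, study, manifest, per_participant)
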