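"""Recording readers/writers and tidy-CSV emitters.

EDF and BrainVision recordings are read through MNE; the package's own
interchange format is columnar CSV (``time_s`` plus one column per
channel, the ECG channel labelled ``ecg_uV``), with markers in a sidecar
``*_markers.csv`` and the cohort STAI table as a flat CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import EcgSignal, EegRecording, SessionRecord

__all__ = ["read_recording", "write_session_csv", "read_session_csv",
           "write_cohort_table", "read_cohort_table"]


def _from_mne_raw(raw, condition: str, breathing_epoch_end):
    data = raw.get_data() * 1e6  # volts -> microvolts
    labels = list(raw.ch_names)
    fs = float(raw.info["sfreq"])
    ecg_idx = [i for i, l in enumerate(labels) if "ecg" in l.lower()]
    markers = []
    ann = raw.annotations
    if ann is not None:
        markers = [(d, float(o)) for d, o in zip(ann.description, ann.onset)]
    if breathing_epoch_end is None:
        for desc, onset in markers:
            if "breathing" in desc.lower():
                breathing_epoch_end = onset
    if ecg_idx:
        i = ecg_idx[0]
        ecg = EcgSignal(data[i], fs, labels[i])
        keep = [j for j in range(len(labels)) if j != i]
        eeg = EegRecording(data[keep], fs, [labels[j] for j in keep], markers)
    else:
        raise ValueError("no ECG channel found in recording")
    return SessionRecord(condition, ecg, eeg, breathing_epoch_end=breathing_epoch_end)


def read_recording(
    path, fmt: str | None = None, condition: str = "control",
    breathing_epoch_end: float | None = None,
) -> SessionRecord:
    """Read a session from EDF, BrainVision or columnar CSV.

    ``fmt`` is inferred from the suffix when omitted.  Unknown channel
    labels pass through with a warning from the reader; missing markers
    mean condition boundaries must come from configuration
    (``breathing_epoch_end``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".edf": "edf", ".vhdr": "brainvision", ".csv": "csv"}.get(path.suffix.lower())
    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return _from_mne_raw(raw, condition, breathing_epoch_end)
    if fmt == "brainvision":
        import mne

        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        return _from_mne_raw(raw, condition, breathing_epoch_end)
    if fmt == "csv":
        return read_session_csv(path, condition, breathing_epoch_end)
    raise ValueError(f"unrecognized recording format for {path}")


def write_session_csv(session: SessionRecord, directory, stem: str) -> dict[str, Path]:
    """Write one session as columnar CSVs (separate ECG and EEG rates).

    Emits ``<stem>_ecg.csv`` (time_s, ecg_uV), ``<stem>_eeg.csv`` (time_s
    + one column per channel) and ``<stem>_markers.csv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    ecg_df = pd.DataFrame({"time_s": session.ecg.times, "ecg_uV": session.ecg.samples})
    p = directory / f"{stem}_ecg.csv"
    ecg_df.to_csv(p, index=False, float_format="%.6f")
    out["ecg"] = p
    eeg = session.eeg
    eeg_df = pd.DataFrame({"time_s": np.arange(eeg.samples.shape[1]) / eeg.sampling_rate})
    for i, ch in enumerate(eeg.channel_labels):
        eeg_df[ch] = eeg.samples[i]
    p = directory / f"{stem}_eeg.csv"
    eeg_df.to_csv(p, index=False, float_format="%.6f")
    out["eeg"] = p
    rows = list(session.eeg.markers)
    if session.condition == "zen" and session.breathing_epoch_end is not None:
        if not any("breathing" in r[0] for r in rows):
            rows.append(("breathing_end", session.breathing_epoch_end))
    p = directory / f"{stem}_markers.csv"
    with open(p, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "time_s"])
        w.writerows(rows)
    out["markers"] = p
    return out


def read_session_csv(
    eeg_path, condition: str = "control", breathing_epoch_end: float | None = None
) -> SessionRecord:
    """Read a session written by :func:`write_session_csv` (pass the
    ``*_eeg.csv`` path; the ``*_ecg.csv``/``*_markers.csv`` siblings are
    found by name)."""
    eeg_path = Path(eeg_path)
    stem = eeg_path.name.removesuffix("_eeg.csv")
    ecg_path = eeg_path.with_name(f"{stem}_ecg.csv")
    marker_path = eeg_path.with_name(f"{stem}_markers.csv")
    eeg_df = pd.read_csv(eeg_path)
    if "time_s" not in eeg_df.columns:
        raise ValueError("missing column 'time_s' in EEG CSV")
    channels = [c for c in eeg_df.columns if c != "time_s"]
    if not channels:
        raise ValueError("missing channel columns in EEG CSV")
    tcol = eeg_df["time_s"].to_numpy()
    fs_eeg = (tcol.size - 1) / float(tcol[-1] - tcol[0])
    markers = []
    if marker_path.exists():
        mdf = pd.read_csv(marker_path)
        markers = [(r.label, float(r.time_s)) for r in mdf.itertuples()]
        if breathing_epoch_end is None:
            for lab, t in markers:
                if "breathing" in str(lab).lower():
                    breathing_epoch_end = t
    eeg = EegRecording(eeg_df[channels].to_numpy().T, round(fs_eeg, 6), channels, markers)
    if not ecg_path.exists():
        raise FileNotFoundError(f"missing ECG sibling file {ecg_path}")
    ecg_df = pd.read_csv(ecg_path)
    for col in ("time_s", "ecg_uV"):
        if col not in ecg_df.columns:
            raise ValueError(f"missing column {col!r} in ECG CSV")
    tecg = ecg_df["time_s"].to_numpy()
    fs_ecg = (tecg.size - 1) / float(tecg[-1] - tecg[0])
    ecg = EcgSignal(ecg_df["ecg_uV"].to_numpy(), round(fs_ecg, 6))
    return SessionRecord(condition, ecg, eeg, breathing_epoch_end=breathing_epoch_end)


def write_cohort_table(records, path) -> Path:
    """Cohort STAI table (id, stai_baseline, stai_before, stai_after, order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "participant": r.id,
            "stai_baseline": r.stai_baseline,
            "stai_before": r.stai_before,
            "stai_after": r.stai_after,
            "condition_order": r.condition_order,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant", "stai_baseline", "stai_before", "stai_after"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing column(s): {sorted(missing)}")
    return df
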