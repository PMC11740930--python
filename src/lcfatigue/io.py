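"""Plain-text readers/writers for the package's on-disk formats.

All formats are CSV with fixed column names (hypnograms: epoch_start_s,
state; events: onset_s, duration_s, kind, modality; photometry: time_s,
f470, f405; corrected traces: time_s, z, masked; recordings: time_s, eeg,
emg). EEG/EMG can also be read from EDF when ``mne`` is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CorrectedTrace, Hypnogram, PhotometryTrace, Recording, StimEvents


def write_hypnogram(hyp: Hypnogram, path) -> None:
    pd.DataFrame({"epoch_start_s": hyp.epoch_starts,
                  "state": hyp.labels}).to_csv(path, index=False)


def read_hypnogram(path) -> Hypnogram:
    df = pd.read_csv(path)
    t0 = float(df["epoch_start_s"].iloc[0]) if len(df) else 0.0
    epoch_s = float(df["epoch_start_s"].iloc[1] - df["epoch_start_s"].iloc[0]) \
        if len(df) > 1 else 5.0
    return Hypnogram.from_labels(df["state"].tolist(), epoch_s=epoch_s, t0=t0)


def write_events(events: StimEvents, path) -> None:
    rows = [{"onset_s": o, "duration_s": events.episode_duration_s,
             "kind": "episode", "modality": events.modality}
            for o in events.episode_onsets_s]
    rows += [{"onset_s": o, "duration_s": d, "kind": "pulse",
              "modality": events.modality}
             for o, d in zip(events.pulse_onsets_s, events.pulse_durations_s)]
    pd.DataFrame(rows).sort_values("onset_s", kind="stable").to_csv(path,
                                                                    index=False)


def read_events(path) -> StimEvents:
    df = pd.read_csv(path)
    eps = df[df["kind"] == "episode"].sort_values("onset_s")
    pls = df[df["kind"] == "pulse"].sort_values("onset_s")
    ep_onsets = eps["onset_s"].to_numpy(dtype=float)
    ep_dur = float(eps["duration_s"].iloc[0]) if len(eps) else 120.0
    p_onsets = pls["onset_s"].to_numpy(dtype=float)
    # Assign each pulse to the last episode starting at or before it.
    idx = np.searchsorted(ep_onsets, p_onsets + 1e-9) - 1
    return StimEvents(
        episode_onsets_s=ep_onsets,
        episode_duration_s=ep_dur,
        pulse_onsets_s=p_onsets,
        pulse_durations_s=pls["duration_s"].to_numpy(dtype=float),
        episode_index_per_pulse=idx,
        modality=str(df["modality"].iloc[0]) if len(df) else "opto",
    )


def write_photometry(trace: PhotometryTrace, path) -> None:
    pd.DataFrame({"time_s": trace.t, "f470": trace.f470,
                  "f405": trace.f405}).to_csv(path, index=False)


def read_photometry(path) -> PhotometryTrace:
    df = pd.read_csv(path)
    return PhotometryTrace(t=df["time_s"].to_numpy(float),
                           f470=df["f470"].to_numpy(float),
                           f405=df["f405"].to_numpy(float))


def write_corrected(ct: CorrectedTrace, path, provenance_path=None) -> None:
    pd.DataFrame({"time_s": ct.t, "z": ct.z,
                  "masked": ct.artifact_mask.astype(int)}).to_csv(path,
                                                                  index=False)
    if provenance_path is not None:
        Path(provenance_path).write_text(
            json.dumps(ct.provenance, indent=2, default=float))


def read_corrected(path) -> CorrectedTrace:
    df = pd.read_csv(path)
    return CorrectedTrace(t=df["time_s"].to_numpy(float),
                          z=df["z"].to_numpy(float),
                          artifact_mask=df["masked"].to_numpy(bool))


def write_recording(rec: Recording, path) -> None:
    pd.DataFrame({"time_s": rec.times, "eeg": rec.eeg,
                  "emg": rec.emg}).to_csv(path, index=False,
                                          float_format="%.5f")


def read_recording(path, eeg_channel: str = "eeg",
                   emg_channel: str = "emg") -> Recording:
    """Read EEG/EMG from CSV (time_s,eeg,emg) or EDF (requires mne)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne  # optional dependency

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return Recording(eeg=raw.get_data(picks=[eeg_channel])[0],
                         emg=raw.get_data(picks=[emg_channel])[0],
                         fs=float(raw.info["sfreq"]))
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    fs = 1.0 / float(t[1] - t[0])
    return Recording(eeg=df["eeg"].to_numpy(float),
                     emg=df["emg"].to_numpy(float), fs=fs, t0=float(t[0]))
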