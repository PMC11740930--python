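"""Core in-memory containers shared across the analysis modules.

All containers hold plain numpy arrays on a common session clock (seconds
from session start). Sleep-wake states are encoded as small integers via
``STATES``; helper methods convert to/from the string labels used in the
on-disk CSV formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Canonical state order used for every probability matrix in the package.
STATES: tuple[str, str, str] = ("Wake", "NREM", "REM")
STATE_TO_CODE = {s: i for i, s in enumerate(STATES)}

EPOCH_S = 5.0  #: scoring epoch length in seconds


@dataclass
class Recording:
    """Raw EEG + EMG session.

    Parameters
    ----------
    eeg, emg
        Equal-length single-channel traces (arbitrary units).
    fs
        Sampling rate in Hz (shared by both channels).
    t0
        Session-clock time of the first sample, seconds.
    """

    eeg: np.ndarray
    emg: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.shape != self.emg.shape:
            raise ValueError("EEG and EMG must have equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.eeg.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.eeg.size) / self.fs


@dataclass
class Hypnogram:
    """Per-epoch sleep-wake labels (Wake/NREM/REM), 5-s epochs.

    ``codes`` holds integer labels indexing into :data:`STATES`.
    """

    codes: np.ndarray
    epoch_s: float = EPOCH_S
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 1:
            raise ValueError("hypnogram codes must be 1-D")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() > 2):
            raise ValueError("state codes must be in {0, 1, 2}")

    @classmethod
    def from_labels(cls, labels: Sequence[str], epoch_s: float = EPOCH_S,
                    t0: float = 0.0) -> "Hypnogram":
        codes = np.array([STATE_TO_CODE[s] for s in labels], dtype=np.int8)
        return cls(codes, epoch_s=epoch_s, t0=t0)

    @property
    def labels(self) -> list[str]:
        return [STATES[c] for c in self.codes]

    @property
    def n_epochs(self) -> int:
        return self.codes.size

    @property
    def epoch_starts(self) -> np.ndarray:
        return self.t0 + self.epoch_s * np.arange(self.codes.size)

    def state_at(self, t: float) -> int:
        """Integer state code of the epoch containing session time ``t``."""
        idx = int(np.floor((t - self.t0) / self.epoch_s))
        if idx < 0 or idx >= self.codes.size:
            raise IndexError(f"time {t} outside hypnogram")
        return int(self.codes[idx])


@dataclass
class StimEvents:
    """Stimulation episode and pulse onset times on the session clock."""

    episode_onsets_s: np.ndarray
    episode_duration_s: float
    pulse_onsets_s: np.ndarray
    pulse_durations_s: np.ndarray
    episode_index_per_pulse: np.ndarray
    modality: str = "opto"

    def __post_init__(self) -> None:
        self.episode_onsets_s = np.asarray(self.episode_onsets_s, dtype=float)
        self.pulse_onsets_s = np.asarray(self.pulse_onsets_s, dtype=float)
        self.pulse_durations_s = np.asarray(self.pulse_durations_s, dtype=float)
        self.episode_index_per_pulse = np.asarray(
            self.episode_index_per_pulse, dtype=int)
        if np.any(np.diff(self.episode_onsets_s) <= 0):
            raise ValueError("episode onsets must be strictly increasing")
        if np.any(np.diff(self.pulse_onsets_s) <= 0):
            raise ValueError("pulse onsets must be strictly increasing")
        if self.pulse_onsets_s.shape != self.pulse_durations_s.shape or \
                self.pulse_onsets_s.shape != self.episode_index_per_pulse.shape:
            raise ValueError("per-pulse arrays must have equal length")

    @property
    def n_episodes(self) -> int:
        return self.episode_onsets_s.size

    @property
    def n_pulses(self) -> int:
        return self.pulse_onsets_s.size

    def pulse_index_within_episode(self) -> np.ndarray:
        """1-based pulse index within each pulse's episode."""
        idx = np.empty(self.n_pulses, dtype=int)
        for ep in range(self.n_episodes):
            sel = self.episode_index_per_pulse == ep
            idx[sel] = np.arange(1, sel.sum() + 1)
        return idx


@dataclass
class PhotometryTrace:
    """Raw two-channel fiber-photometry session (470 nm + 405 nm)."""

    t: np.ndarray
    f470: np.ndarray
    f405: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f470 = np.asarray(self.f470, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        if not (self.t.shape == self.f470.shape == self.f405.shape):
            raise ValueError("t, f470, f405 must have equal length")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if dt.min() <= 0:
                raise ValueError("t must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("t must be uniformly sampled")

    @property
    def fs(self) -> float:
        if self.t.size < 2:
            raise ValueError("need at least two samples to infer fs")
        return 1.0 / float(self.t[1] - self.t[0])


@dataclass
class CorrectedTrace:
    """Artifact-corrected, bleach-corrected, z-scored photometry signal."""

    t: np.ndarray
    z: np.ndarray
    artifact_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if not (self.t.shape == self.z.shape == self.artifact_mask.shape):
            raise ValueError("t, z, mask must have equal length")

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])
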