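"""Raw EEG/EMG synthesis from a ground-truth hypnogram.

The EEG is a sum of three independent band-limited noise streams — a delta
band (1-5 Hz), a theta band (6-9 Hz), and a broadband floor — whose
amplitudes follow per-state gain envelopes, so each state carries the
spectral signature the staging criteria look for: NREM rich in delta,
REM rich in theta with low delta, Wake intermediate with low delta.
The EMG is white noise with a per-state RMS envelope, highest in Wake.
Gain envelopes are cross-faded over a short window at epoch boundaries so
the synthesized traces have no step discontinuities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from ..core import Hypnogram, Recording


def _default_eeg_gains() -> dict:
    # Amplitude multipliers per state for (delta, theta, broadband) streams.
    return {
        "Wake": (1.0, 1.0, 1.0),
        "NREM": (4.0, 0.8, 0.8),
        "REM": (0.6, 2.5, 0.7),
    }


def _default_emg_rms() -> dict:
    return {"Wake": 3.0, "NREM": 0.5, "REM": 0.35}


@dataclass
class SignalModelParams:
    """Raw-signal model: sampling rates, spectral profiles, bleach/artifact/noise.

    The EEG/EMG fields are used by :func:`synthesize_eeg_emg`; the
    photometry fields live in
    :class:`~lcfatigue.synthgen.photometry.PhotometrySynthParams`.
    """

    eeg_fs_hz: float = 1500.0
    photometry_fs_hz: float = 10.0
    eeg_gains: dict = field(default_factory=_default_eeg_gains)
    emg_rms: dict = field(default_factory=_default_emg_rms)
    delta_band_hz: tuple = (1.0, 5.0)
    theta_band_hz: tuple = (6.0, 9.0)
    broadband_hz: tuple = (0.5, 45.0)
    crossfade_s: float = 0.25     #: gain-envelope smoothing at epoch boundaries

    def __post_init__(self) -> None:
        if self.eeg_fs_hz <= 0 or self.photometry_fs_hz <= 0:
            raise ValueError("sampling rates must be positive")
        if not self.eeg_gains["NREM"][0] > self.eeg_gains["Wake"][0]:
            raise ValueError("NREM delta gain must exceed Wake delta gain")
        if not (self.emg_rms["Wake"] > self.emg_rms["NREM"] and
                self.emg_rms["Wake"] > self.emg_rms["REM"]):
            raise ValueError("Wake EMG RMS must exceed sleep EMG RMS")


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise."""
    x = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return y / max(np.std(y), 1e-12)


def _gain_envelope(per_epoch: np.ndarray, samples_per_epoch: int,
                   fade_samples: int) -> np.ndarray:
    env = np.repeat(per_epoch, samples_per_epoch)
    if fade_samples > 1:
        kernel = np.ones(fade_samples) / fade_samples
        env = np.convolve(env, kernel, mode="same")
    return env


def synthesize_eeg_emg(hypnogram: Hypnogram, params: SignalModelParams,
                       seed: int | np.random.Generator) -> Recording:
    """Build a raw EEG+EMG recording whose epochs carry the hypnogram's states."""
    if hypnogram.n_epochs == 0:
        raise ValueError("hypnogram must be nonempty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = params.eeg_fs_hz
    spe = int(round(hypnogram.epoch_s * fs))
    n = spe * hypnogram.n_epochs
    fade = int(round(params.crossfade_s * fs))

    states = ("Wake", "NREM", "REM")
    codes = hypnogram.codes
    gains = np.array([params.eeg_gains[s] for s in states])  # (3 states, 3 streams)
    bands = (params.delta_band_hz, params.theta_band_hz, params.broadband_hz)

    eeg = np.zeros(n)
    for j, band in enumerate(bands):
        stream = _band_noise(rng, n, fs, band)
        env = _gain_envelope(gains[codes, j], spe, fade)
        eeg += stream * env

    emg_levels = np.array([params.emg_rms[s] for s in states])
    emg_env = _gain_envelope(emg_levels[codes], spe, fade)
    emg = rng.standard_normal(n) * emg_env
    return Recording(eeg=eeg, emg=emg, fs=fs, t0=hypnogram.t0)
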