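"""Sleep-wake staging from EEG/EMG.

Each 5-s epoch is classified as Wake, NREM, or REM from three features:
EMG root-mean-square (muscle tone), EEG delta power (summed spectral power,
1-5 Hz) and the theta/delta power ratio (theta: 6-9 Hz). Rules are applied
in fixed precedence: high muscle tone -> Wake; else high delta -> NREM;
else high theta/delta -> REM; else the previous epoch's label is carried
forward (the first unresolved epoch defaults to Wake).

Spectral estimates use an averaged periodogram (Welch) with 2-s Hann
segments at 50% overlap within each epoch, giving 0.5-Hz bins; band power
sums bins whose center frequencies lie inside the band, endpoints included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import EPOCH_S, Hypnogram, Recording

DELTA_BAND = (1.0, 5.0)
THETA_BAND = (6.0, 9.0)


class InsufficientBandwidthError(ValueError):
    """Sampling rate too low to resolve the theta band."""


class ThresholdUndefinedError(ValueError):
    """Feature distribution too degenerate to derive thresholds."""


@dataclass
class EpochFeatures:
    """Per-epoch staging features (arrays of equal length)."""

    delta_power: np.ndarray
    theta_power: np.ndarray
    emg_rms: np.ndarray
    epoch_s: float = EPOCH_S
    t0: float = 0.0

    @property
    def theta_delta_ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.delta_power > 0,
                            self.theta_power / self.delta_power, np.inf)

    @property
    def n_epochs(self) -> int:
        return self.delta_power.size


@dataclass
class StagingThresholds:
    emg_wake_threshold: float
    delta_nrem_threshold: float
    theta_delta_rem_threshold: float

    def __post_init__(self) -> None:
        for name in ("emg_wake_threshold", "delta_nrem_threshold",
                     "theta_delta_rem_threshold"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive")


def compute_epoch_features(recording: Recording,
                           epoch_s: float = EPOCH_S) -> EpochFeatures:
    """Delta power, theta power and EMG RMS for every whole epoch."""
    fs = recording.fs
    if fs < 2 * THETA_BAND[1]:
        raise InsufficientBandwidthError(
            f"fs={fs} Hz cannot resolve the {THETA_BAND[1]}-Hz band edge")
    spe = int(round(epoch_s * fs))
    n_epochs = recording.eeg.size // spe
    if n_epochs < 1:
        raise ValueError("need at least one whole epoch")

    eeg = recording.eeg[: n_epochs * spe].reshape(n_epochs, spe)
    emg = recording.emg[: n_epochs * spe].reshape(n_epochs, spe)

    nperseg = min(int(round(2 * fs)), spe)
    freqs, psd = sps.welch(eeg, fs=fs, nperseg=nperseg,
                           noverlap=nperseg // 2, axis=-1)
    delta_sel = (freqs >= DELTA_BAND[0]) & (freqs <= DELTA_BAND[1])
    theta_sel = (freqs >= THETA_BAND[0]) & (freqs <= THETA_BAND[1])
    return EpochFeatures(
        delta_power=psd[:, delta_sel].sum(axis=1),
        theta_power=psd[:, theta_sel].sum(axis=1),
        emg_rms=np.sqrt(np.mean(emg ** 2, axis=1)),
        epoch_s=epoch_s,
        t0=recording.t0,
    )


def _bimodal_split(values: np.ndarray, log: bool = True,
                   random_state: int = 0) -> float:
    """Midpoint between the two modes of a two-component Gaussian-mixture
    split (on the log scale by default); raises if degenerate."""
    from sklearn.mixture import GaussianMixture

    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if log:
        x = x[x > 0]
        x = np.log(x)
    if x.size < 10 or np.ptp(x) < 1e-12:
        raise ThresholdUndefinedError("feature distribution is degenerate")
    gm = GaussianMixture(n_components=2, n_init=3, random_state=random_state)
    gm.fit(x.reshape(-1, 1))
    means = np.sort(gm.means_.ravel())
    if means[1] - means[0] < 1e-9:
        raise ThresholdUndefinedError("mixture modes coincide")
    mid = means.mean()
    return float(np.exp(mid)) if log else float(mid)


def auto_thresholds(features: EpochFeatures) -> StagingThresholds:
    """Derive staging thresholds from the session's own feature distributions.

    The EMG threshold splits the (log) muscle-tone distribution into its
    sleep and wake modes; the delta and theta/delta thresholds are then
    derived the same way from the low-EMG (sleep) epochs only, separating
    NREM from REM.
    """
    if features.n_epochs < 100:
        raise ValueError("need at least 100 epochs to derive thresholds")
    emg_thr = _bimodal_split(features.emg_rms, log=True)
    sleep = features.emg_rms < emg_thr
    if sleep.sum() < 10:
        raise ThresholdUndefinedError("too few sleep epochs below EMG threshold")
    delta_thr = _bimodal_split(features.delta_power[sleep], log=True)
    ratio = features.theta_delta_ratio[sleep]
    ratio_thr = _bimodal_split(ratio[np.isfinite(ratio)], log=True)
    return StagingThresholds(emg_wake_threshold=emg_thr,
                             delta_nrem_threshold=delta_thr,
                             theta_delta_rem_threshold=ratio_thr)


def classify_epochs(features: EpochFeatures, thresholds: StagingThresholds,
                    carry_forward: bool = True) -> Hypnogram:
    """Apply the staging rules in precedence order.

    With ``carry_forward`` disabled, epochs failing all three rules are
    labeled Wake instead of inheriting the previous label (useful to verify
    that the classifier is otherwise memoryless).
    """
    n = features.n_epochs
    ratio = features.theta_delta_ratio
    codes = np.empty(n, dtype=np.int8)
    prev = 0  # first unresolved epoch defaults to Wake
    for i in range(n):
        if features.emg_rms[i] >= thresholds.emg_wake_threshold:
            codes[i] = 0
        elif features.delta_power[i] >= thresholds.delta_nrem_threshold:
            codes[i] = 1
        elif ratio[i] >= thresholds.theta_delta_rem_threshold:
            codes[i] = 2
        else:
            codes[i] = prev if carry_forward else 0
        prev = codes[i]
    return Hypnogram(codes, epoch_s=features.epoch_s, t0=features.t0)


def stage_recording(recording: Recording,
                    thresholds: StagingThresholds | None = None,
                    epoch_s: float = EPOCH_S) -> tuple[Hypnogram, StagingThresholds]:
    """Features -> (auto) thresholds -> hypnogram, in one call."""
    feats = compute_epoch_features(recording, epoch_s=epoch_s)
    thr = thresholds or auto_thresholds(feats)
    return classify_epochs(feats, thr), thr


def normalized_spectrogram(recording: Recording, bin_s: float = EPOCH_S,
                           max_freq_hz: float | None = None
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin EEG power spectra scaled by the single session-wide maximum.

    Returns ``(times, freqs, S)`` with S in [0, 1] and max(S) == 1; suitable
    for session-overview displays where absolute power is irrelevant.
    """
    fs = recording.fs
    spe = int(round(bin_s * fs))
    n_bins = recording.eeg.size // spe
    if n_bins < 1:
        raise ValueError("need at least one bin")
    eeg = recording.eeg[: n_bins * spe].reshape(n_bins, spe)
    nperseg = min(int(round(2 * fs)), spe)
    freqs, psd = sps.welch(eeg, fs=fs, nperseg=nperseg,
                           noverlap=nperseg // 2, axis=-1)
    if max_freq_hz is not None:
        sel = freqs <= max_freq_hz
        freqs, psd = freqs[sel], psd[:, sel]
    peak = psd.max()
    if peak <= 0:
        raise ValueError("all-zero signal: normalization undefined")
    times = recording.t0 + bin_s * np.arange(n_bins)
    return times, freqs, psd / peak
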