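"""Fiber-photometry preprocessing.

Converts a raw two-channel (470/405 nm) trace into a single corrected,
z-scored signal:

1. derivative-threshold artifact removal on each raw channel (movement and
   shaker transients are far faster than calcium or NE dynamics),
2. biexponential photobleaching fit and subtraction per channel,
3. isosbestic correction — ordinary least squares of the detrended 405-nm
   channel onto the detrended 470-nm channel over the whole session, with
   the fitted component subtracted,
4. z-scoring over non-masked samples (SD with denominator n-1).

A zero-phase 0.2-Hz low-pass is provided for display; it is never applied
before pulse quantification. Every step records its parameters in a
provenance dict so a rerun is bit-identical and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal as sps

from .core import CorrectedTrace, PhotometryTrace


@dataclass
class BleachFit:
    """Biexponential bleach model B(t) = A1 e^(-t/tau1) + A2 e^(-t/tau2) + c."""

    A1: float
    tau1_s: float
    A2: float
    tau2_s: float
    offset: float
    residual_rms: float
    fallback_single_exp: bool = False

    def curve(self, t: np.ndarray) -> np.ndarray:
        return (self.A1 * np.exp(-t / self.tau1_s)
                + self.A2 * np.exp(-t / self.tau2_s) + self.offset)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("A1", "tau1_s", "A2", "tau2_s", "offset", "residual_rms",
                 "fallback_single_exp")}


def _biexp(t, a1, tau1, a2, tau2, c):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


# (fast, slow) tau starting pairs spanning roughly 1-100 minutes.
_TAU_STARTS = ((60.0, 1800.0), (120.0, 3600.0), (300.0, 6000.0), (30.0, 600.0))


def fit_bleach(t: np.ndarray, channel: np.ndarray,
               min_duration_s: float = 600.0,
               max_fit_points: int = 3000) -> tuple[BleachFit, np.ndarray]:
    """Fit and subtract the slow photobleaching decay of one channel.

    Multi-start nonlinear least squares with positivity bounds on both time
    constants; the best-residual start wins. Long traces are fitted on an
    evenly decimated subset (deterministic) and evaluated at full
    resolution. If no biexponential start converges, a single exponential
    plus offset is used and flagged.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(channel, dtype=float)
    if t[-1] - t[0] < min_duration_s:
        raise ValueError(f"need at least {min_duration_s} s of data")
    step = max(1, t.size // max_fit_points)
    tf, yf = t[::step], y[::step]

    # Fit on a gain-normalized copy so the result is exactly equivariant
    # under overall scaling of the raw channel.
    scale = float(np.std(yf))
    scale = scale if scale > 0 else 1.0
    yf = yf / scale

    span = max(np.ptp(yf), 1e-9)
    tail = float(np.mean(yf[-max(1, yf.size // 20):]))
    best = None
    for tau1, tau2 in _TAU_STARTS:
        p0 = (0.7 * span, tau1, 0.3 * span, tau2, tail)
        try:
            popt, _ = optimize.curve_fit(
                _biexp, tf, yf, p0=p0,
                bounds=([-np.inf, 1e-3, -np.inf, 1e-3, -np.inf],
                        [np.inf, np.inf, np.inf, np.inf, np.inf]),
                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rms = float(np.sqrt(np.mean((yf - _biexp(tf, *popt)) ** 2)))
        if best is None or rms < best[1]:
            best = (popt, rms)

    if best is not None:
        a1, tau1, a2, tau2, c = best[0]
        fit = BleachFit(float(a1 * scale), float(tau1), float(a2 * scale),
                        float(tau2), float(c * scale), residual_rms=0.0)
    else:
        def _single(tt, a, tau, c):
            return a * np.exp(-tt / tau) + c
        popt, _ = optimize.curve_fit(
            _single, tf, yf, p0=(span, 1800.0, tail),
            bounds=([-np.inf, 1e-3, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000)
        a, tau, c = popt
        fit = BleachFit(float(a * scale), float(tau), 0.0, float(2 * tau),
                        float(c * scale), residual_rms=0.0,
                        fallback_single_exp=True)

    detrended = y - fit.curve(t)
    fit.residual_rms = float(np.sqrt(np.mean(detrended ** 2)))
    return fit, detrended


def remove_artifacts(channel: np.ndarray, k_mad: float = 8.0
                     ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Mask and interpolate fast transients via a first-difference threshold.

    Samples whose absolute first difference exceeds ``k_mad`` times the MAD
    of the absolute differences are masked together with one neighbor on
    each side, then linearly interpolated. Returns
    ``(cleaned, mask, info)``; ``info['high_mask_fraction']`` warns when
    more than 20% of samples were masked.
    """
    y = np.asarray(channel, dtype=float)
    info = {"k_mad": k_mad, "high_mask_fraction": False, "n_masked": 0}
    mask = np.zeros(y.size, dtype=bool)
    if not np.isfinite(k_mad) or y.size < 3:
        return y.copy(), mask, info
    d = np.abs(np.diff(y))
    mad = float(np.median(np.abs(d - np.median(d))))
    if mad <= 0:
        return y.copy(), mask, info
    bad = d > k_mad * mad
    # Each offending difference implicates both of its samples.
    mask[:-1] |= bad
    mask[1:] |= bad
    # One extra neighbor on each side.
    grown = mask.copy()
    grown[:-1] |= mask[1:]
    grown[1:] |= mask[:-1]
    mask = grown
    info["n_masked"] = int(mask.sum())
    info["high_mask_fraction"] = bool(mask.mean() > 0.20)
    cleaned = y.copy()
    if mask.any() and not mask.all():
        idx = np.arange(y.size)
        cleaned[mask] = np.interp(idx[mask], idx[~mask], y[~mask])
    return cleaned, mask, info


def isosbestic_correct(det470: np.ndarray, det405: np.ndarray
                       ) -> tuple[np.ndarray, dict]:
    """Regress the isosbestic channel out of the signal channel.

    OLS of det470 on det405 (slope + intercept, whole session); corrected =
    det470 - (slope * det405 + intercept). A constant 405 channel degrades
    to mean-centering of the 470 channel, flagged in the returned info.
    """
    x = np.asarray(det405, dtype=float)
    y = np.asarray(det470, dtype=float)
    if x.shape != y.shape:
        raise ValueError("channels must have equal length")
    info: dict = {"degenerate_isosbestic": False}
    if np.ptp(x) < 1e-12:
        info.update(degenerate_isosbestic=True, slope=0.0,
                    intercept=float(np.mean(y)))
        return y - np.mean(y), info
    slope, intercept = np.polyfit(x, y, 1)
    info.update(slope=float(slope), intercept=float(intercept))
    return y - (slope * x + intercept), info


def zscore(corrected: np.ndarray, mask: np.ndarray | None = None
           ) -> tuple[np.ndarray, dict]:
    """Z-score using non-masked samples only (ddof=1)."""
    y = np.asarray(corrected, dtype=float)
    m = np.zeros(y.size, dtype=bool) if mask is None else np.asarray(mask, bool)
    good = y[~m]
    if good.size < 2:
        raise ValueError("need at least two non-masked samples")
    sd = float(np.std(good, ddof=1))
    if sd == 0:
        raise ValueError("zero variance: z-score undefined")
    mu = float(np.mean(good))
    return (y - mu) / sd, {"mean": mu, "sd": sd, "ddof": 1}


def lowpass_02hz(z: np.ndarray, fs: float = 10.0, cutoff_hz: float = 0.2,
                 order: int = 4) -> np.ndarray:
    """Zero-phase low-pass with -3 dB at ``cutoff_hz`` (display only).

    The Butterworth corner is pre-warped so the *two-pass* (filtfilt)
    magnitude hits -3 dB at the nominal cutoff.
    """
    y = np.asarray(z, dtype=float)
    # |H|^2 at cutoff must be 1/sqrt(2): corner = cutoff / (sqrt(2)-1)^(1/2N)
    corner = cutoff_hz / (np.sqrt(2.0) - 1.0) ** (1.0 / (2 * order))
    sos = sps.butter(order, corner, btype="lowpass", fs=fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if y.size <= 3 * padlen:
        raise ValueError("trace too short for zero-phase filtering")
    return sps.sosfiltfilt(sos, y)


def preprocess(trace: PhotometryTrace, k_mad: float = 8.0,
               apply_lowpass: bool = False) -> CorrectedTrace:
    """Full correction chain: artifacts -> bleach -> isosbestic -> z-score."""
    c470, m470, i470 = remove_artifacts(trace.f470, k_mad=k_mad)
    c405, m405, i405 = remove_artifacts(trace.f405, k_mad=k_mad)
    mask = m470 | m405
    fit470, det470 = fit_bleach(trace.t, c470)
    fit405, det405 = fit_bleach(trace.t, c405)
    corrected, reg = isosbestic_correct(det470, det405)
    z, zinfo = zscore(corrected, mask)
    if apply_lowpass:
        z = lowpass_02hz(z, fs=trace.fs)
    provenance = {
        "order": ["remove_artifacts", "fit_bleach", "isosbestic_correct",
                  "zscore"] + (["lowpass_02hz"] if apply_lowpass else []),
        "artifacts_470": i470,
        "artifacts_405": i405,
        "bleach_470": fit470.as_dict(),
        "bleach_405": fit405.as_dict(),
        "isosbestic": reg,
        "zscore": zinfo,
    }
    return CorrectedTrace(t=trace.t, z=z, artifact_mask=mask,
                          provenance=provenance)
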