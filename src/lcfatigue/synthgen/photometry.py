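"""Raw two-channel fiber-photometry synthesis.

The 470-nm (ligand-dependent) channel is built as

    bleach(t) + state_baseline(t) + sum_k amp_k * kernel(t - t_k)
    + motion(t) + noise

where ``bleach`` is a biexponential photobleaching decay, ``state_baseline``
tracks the hypnogram (LC activity and NE are higher in Wake), ``kernel`` is
a saturating rise during the 2-s pulse followed by an exponential decay
(slower for the NE sensor than for calcium), and ``motion`` is a shared
movement-artifact process. The 405-nm (isosbestic) channel carries its own
bleach, a scaled copy of the same motion artifacts, and noise — but no
response component, which is what makes regression-based correction work.
Mechanical (shaker) sessions additionally get sharp one-to-two-sample
spikes on both channels at stimulus onsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import Hypnogram, PhotometryTrace, StimEvents


def _default_bleach_470() -> tuple:
    return (30.0, 2400.0, 8.0, 400.0, 100.0)   # A1, tau1_s, A2, tau2_s, offset


def _default_bleach_405() -> tuple:
    return (20.0, 2000.0, 5.0, 350.0, 80.0)


def _default_state_baseline() -> dict:
    # Baseline shift (response-amplitude units) per state; Wake highest.
    return {"Wake": 0.15, "NREM": 0.0, "REM": -0.05}


@dataclass
class PhotometrySynthParams:
    """Generative parameters for the raw 470/405 channels."""

    fs_hz: float = 10.0
    bleach_470: tuple = field(default_factory=_default_bleach_470)
    bleach_405: tuple = field(default_factory=_default_bleach_405)
    state_baseline: dict = field(default_factory=_default_state_baseline)
    baseline_smooth_s: float = 5.0
    tau_rise_s: float = 0.2        #: kernel rise constant (calcium default)
    tau_decay_s: float = 0.6       #: kernel decay constant (calcium default)
    artifact_rate_per_min: float = 2.0
    artifact_amp: float = 3.0      #: SD of shared motion-artifact amplitude
    artifact_scale_405: float = 0.8
    mech_spike_amp: float = 5.0    #: shaker-onset spike amplitude (mechanical only)
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        a1, t1, a2, t2, _ = self.bleach_470
        if t1 == t2:
            raise ValueError("bleach time constants must differ")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @classmethod
    def for_sensor(cls, sensor: str, **kwargs) -> "PhotometrySynthParams":
        """Sensor presets: 'calcium' (fast kernel) or 'ne' (slower GRAB kinetics)."""
        if sensor == "calcium":
            defaults = dict(tau_rise_s=0.2, tau_decay_s=0.6)
        elif sensor == "ne":
            defaults = dict(tau_rise_s=0.5, tau_decay_s=1.2)
        else:
            raise ValueError("sensor must be 'calcium' or 'ne'")
        defaults.update(kwargs)
        return cls(**defaults)


def response_kernel(t_rel: np.ndarray, pulse_duration_s: float,
                    tau_rise_s: float, tau_decay_s: float) -> np.ndarray:
    """Unit-peak response kernel: saturating rise over the pulse, then decay."""
    t = np.asarray(t_rel, dtype=float)
    rise_end = 1.0 - np.exp(-pulse_duration_s / tau_rise_s)
    out = np.zeros_like(t)
    in_pulse = (t >= 0) & (t <= pulse_duration_s)
    out[in_pulse] = (1.0 - np.exp(-t[in_pulse] / tau_rise_s)) / rise_end
    after = t > pulse_duration_s
    out[after] = np.exp(-(t[after] - pulse_duration_s) / tau_decay_s)
    return out


def synthesize_photometry(events: StimEvents, amplitudes: np.ndarray,
                          params: PhotometrySynthParams,
                          session_length_s: float,
                          seed: int | np.random.Generator,
                          hypnogram: Hypnogram | None = None) -> PhotometryTrace:
    """Render raw 470/405 traces from programmed per-pulse amplitudes.

    ``amplitudes`` has one entry per pulse in ``events`` (the ground-truth
    C_k or N_k). Deterministic given ``seed``.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.size != events.n_pulses:
        raise ValueError("need one amplitude per pulse")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = params.fs_hz
    n = int(round(session_length_s * fs))
    t = np.arange(n) / fs

    a1, tau1, a2, tau2, off = params.bleach_470
    f470 = a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + off
    b1, bt1, b2, bt2, boff = params.bleach_405
    f405 = b1 * np.exp(-t / bt1) + b2 * np.exp(-t / bt2) + boff

    # State-dependent baseline on the signal channel only.
    if hypnogram is not None and params.state_baseline:
        levels = np.array([params.state_baseline[s] for s in ("Wake", "NREM", "REM")])
        per_epoch = levels[hypnogram.codes]
        env = np.repeat(per_epoch, int(round(hypnogram.epoch_s * fs)))
        env = env[:n] if env.size >= n else np.pad(env, (0, n - env.size), "edge")
        w = max(1, int(round(params.baseline_smooth_s * fs)))
        f470 += np.convolve(env, np.ones(w) / w, mode="same")

    # Evoked responses (470 only).
    for onset, dur, amp in zip(events.pulse_onsets_s, events.pulse_durations_s,
                               amplitudes):
        i0 = int(np.ceil((onset - 1e-9) * fs))
        i1 = min(n, int(np.ceil((onset + dur + 6 * params.tau_decay_s) * fs)))
        if i0 >= n:
            continue
        tr = t[i0:i1] - onset
        f470[i0:i1] += amp * response_kernel(tr, dur, params.tau_rise_s,
                                             params.tau_decay_s)

    # Shared motion artifacts: Poisson-timed 1-2 sample deflections.
    n_art = rng.poisson(params.artifact_rate_per_min * session_length_s / 60.0)
    if params.artifact_amp > 0 and n_art > 0:
        pos = rng.integers(0, n - 1, size=n_art)
        amp_art = params.artifact_amp * rng.standard_normal(n_art)
        width = rng.integers(1, 3, size=n_art)
        art = np.zeros(n)
        for p, a, w in zip(pos, amp_art, width):
            art[p:p + int(w)] += a
        f470 += art
        f405 += params.artifact_scale_405 * art

    # Shaker onsets produce sharp spikes on both channels.
    if events.modality == "mechanical" and params.mech_spike_amp > 0:
        spike = np.zeros(n)
        for onset in events.pulse_onsets_s:
            i0 = int(np.round(onset * fs))
            if 0 <= i0 < n:
                w = int(rng.integers(1, 3))
                spike[i0:i0 + w] += params.mech_spike_amp * rng.choice([-1.0, 1.0])
        f470 += spike
        f405 += params.artifact_scale_405 * spike

    if params.noise_sd > 0:
        f470 += params.noise_sd * rng.standard_normal(n)
        f405 += params.noise_sd * rng.standard_normal(n)
    return PhotometryTrace(t=t, f470=f470, f405=f405)
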