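"""Stimulation protocol builder.

The reference protocol delivers 2-min stimulation episodes repeated every
10 min (24 episodes per session). Within each episode, 2-s pulses recur with
inter-onset intervals drawn uniformly from mean +/- jitter (10 +/- 5 s by
default), the first pulse anchored at the episode onset. A continuous 10-Hz
train mode is represented at episode granularity only (a single effective
drive per episode); pulse-resolved analysis applies to the intermittent mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import StimEvents


class ProtocolInfeasibleError(ValueError):
    """Session too short to accommodate the requested episodes."""


@dataclass
class StimProtocol:
    """Stimulation schedule parameters (all durations in seconds)."""

    episode_duration_s: float = 120.0
    inter_episode_onset_s: float = 600.0
    n_episodes: int = 24
    mode: str = "pulse"            # "pulse" (intermittent 2-s) or "train"
    pulse_duration_s: float = 2.0
    inter_pulse_mean_s: float = 10.0
    inter_pulse_jitter_s: float = 5.0   # uniform +/- jitter on the interval
    train_freq_hz: float = 10.0
    train_pulse_width_ms: float = 10.0
    modality: str = "opto"         # "opto" or "mechanical"
    time_resolution_s: float = 0.1  # TTL command clock granularity

    def __post_init__(self) -> None:
        if self.episode_duration_s >= self.inter_episode_onset_s:
            raise ValueError("episodes must be shorter than their spacing")
        if self.inter_pulse_jitter_s >= self.inter_pulse_mean_s:
            raise ValueError("inter-pulse jitter must be below the mean interval")
        for name in ("episode_duration_s", "inter_episode_onset_s",
                     "pulse_duration_s", "inter_pulse_mean_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.inter_pulse_jitter_s < 0:
            raise ValueError("jitter must be nonnegative")
        if self.mode not in ("pulse", "train"):
            raise ValueError("mode must be 'pulse' or 'train'")
        if self.modality not in ("opto", "mechanical"):
            raise ValueError("modality must be 'opto' or 'mechanical'")
        if self.n_episodes < 1:
            raise ValueError("need at least one episode")


def generate_protocol(protocol: StimProtocol, session_length_s: float,
                      seed: int | np.random.Generator) -> StimEvents:
    """Realize a :class:`StimProtocol` into concrete event times.

    Pulse onsets within each episode form a renewal process with
    inter-onset intervals uniform on [mean - jitter, mean + jitter]; the
    first pulse sits at the episode onset and no pulse starts unless it
    fits entirely inside the episode. Deterministic given ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if session_length_s < protocol.n_episodes * protocol.inter_episode_onset_s:
        raise ProtocolInfeasibleError(
            f"session of {session_length_s} s cannot hold "
            f"{protocol.n_episodes} episodes every {protocol.inter_episode_onset_s} s")

    episode_onsets = protocol.inter_episode_onset_s * np.arange(protocol.n_episodes)
    pulse_onsets: list[float] = []
    pulse_durations: list[float] = []
    episode_index: list[int] = []

    if protocol.mode == "train":
        # Continuous 10-Hz train: one effective drive spanning the episode.
        for ep, onset in enumerate(episode_onsets):
            pulse_onsets.append(float(onset))
            pulse_durations.append(protocol.episode_duration_s)
            episode_index.append(ep)
    else:
        lo = protocol.inter_pulse_mean_s - protocol.inter_pulse_jitter_s
        hi = protocol.inter_pulse_mean_s + protocol.inter_pulse_jitter_s
        res = protocol.time_resolution_s
        last_start = protocol.episode_duration_s - protocol.pulse_duration_s
        for ep, onset in enumerate(episode_onsets):
            t = 0.0
            while t <= last_start + 1e-12:
                pulse_onsets.append(float(onset + t))
                pulse_durations.append(protocol.pulse_duration_s)
                episode_index.append(ep)
                gap = float(rng.uniform(lo, hi)) if hi > lo else lo
                if res > 0:  # events commanded on the TTL clock grid
                    gap = max(lo, round(gap / res) * res)
                t += gap

    return StimEvents(
        episode_onsets_s=episode_onsets,
        episode_duration_s=protocol.episode_duration_s,
        pulse_onsets_s=np.array(pulse_onsets),
        pulse_durations_s=np.array(pulse_durations),
        episode_index_per_pulse=np.array(episode_index, dtype=int),
        modality=protocol.modality,
    )
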