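"""Activity-dependent fatigue of evoked calcium and NE responses.

A single latent inhibition variable ``a`` stands in for NE-dependent
autoinhibition of LC neurons through Gi-coupled alpha-2A autoreceptors:
each pulse's NE output increments ``a`` (scaled down in knockdown cohorts),
``a`` recovers exponentially between pulses, and a larger ``a``
multiplicatively suppresses both the calcium response and — more strongly —
the NE released per unit calcium. The model is deterministic; it is the
simplest mechanism producing the three qualitative facts it must emulate:
within-episode response decline, NE declining faster than calcium, and
attenuated decline when autoreceptor feedback is weakened.

Update rules, for pulse k at time t_k with preceding pulse at t_{k-1}:

    a   <- a * exp(-(t_k - t_{k-1}) / tau_a)
    C_k  = c0 * max(floor_ca, 1 - kappa_ca * a)
    N_k  = n0 * (C_k / c0) * max(floor_ne, 1 - kappa_ne * a)
    a   <- a + gamma * kd_factor * N_k
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import StimEvents


@dataclass
class FatigueParams:
    """Parameters of the scalar-inhibition fatigue model (unitless unless noted)."""

    a0: float = 0.0            #: initial inhibition
    tau_a_s: float = 60.0      #: inhibition recovery time constant, seconds
    gamma: float = 1.1         #: inhibition increment per unit NE released
    kappa_ca: float = 0.35     #: calcium suppression gain
    kappa_ne: float = 0.70     #: NE suppression gain (>= kappa_ca)
    floor_ca: float = 0.05     #: minimum fractional calcium amplitude
    floor_ne: float = 0.02     #: minimum fractional NE amplitude
    c0: float = 1.0            #: unit calcium amplitude
    n0: float = 1.0            #: unit NE amplitude
    kd_factor: float = 1.0     #: gamma multiplier for knockdown cohorts (1 = control)

    def __post_init__(self) -> None:
        if not (self.kappa_ne >= self.kappa_ca >= 0):
            raise ValueError("require kappa_ne >= kappa_ca >= 0 "
                             "(NE declines at least as fast as calcium)")
        for name in ("floor_ca", "floor_ne"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.tau_a_s <= 0:
            raise ValueError("tau_a_s must be positive")
        if not (0 <= self.kd_factor <= 1):
            raise ValueError("kd_factor must be in [0, 1]")
        if self.gamma < 0 or self.a0 < 0:
            raise ValueError("gamma and a0 must be nonnegative")


@dataclass
class FatigueResult:
    """Per-pulse amplitudes and the latent inhibition trajectory."""

    calcium: np.ndarray      #: C_k, one per pulse
    ne: np.ndarray           #: N_k, one per pulse
    a_pre: np.ndarray        #: inhibition just before each pulse
    a_post: np.ndarray       #: inhibition just after each pulse

    def per_episode(self, events: StimEvents, which: str = "ne") -> list[np.ndarray]:
        """Amplitudes grouped by episode, in pulse order."""
        x = self.ne if which == "ne" else self.calcium
        return [x[events.episode_index_per_pulse == ep]
                for ep in range(events.n_episodes)]


def simulate_fatigue(events: StimEvents, params: FatigueParams) -> FatigueResult:
    """Run the inhibition recursion over all pulses of a session.

    Deterministic. Inhibition decays across inter-episode gaps exactly as it
    does between pulses (same time constant), so early-session episodes start
    nearly fresh while closely spaced pulses accumulate inhibition.
    """
    if events.n_pulses == 0:
        raise ValueError("events must contain at least one pulse")
    t = events.pulse_onsets_s
    n = t.size
    C = np.empty(n)
    N = np.empty(n)
    a_pre = np.empty(n)
    a_post = np.empty(n)
    a = float(params.a0)
    g_eff = params.gamma * params.kd_factor
    prev_t = t[0]
    for k in range(n):
        a *= np.exp(-(t[k] - prev_t) / params.tau_a_s)
        a_pre[k] = a
        C[k] = params.c0 * max(params.floor_ca, 1.0 - params.kappa_ca * a)
        N[k] = params.n0 * (C[k] / params.c0) * \
            max(params.floor_ne, 1.0 - params.kappa_ne * a)
        a += g_eff * N[k]
        a_post[k] = a
        prev_t = t[k]
    return FatigueResult(calcium=C, ne=N, a_pre=a_pre, a_post=a_post)


def ne_per_epoch(events: StimEvents, ne_amplitudes: np.ndarray,
                 n_epochs: int, epoch_s: float = 5.0) -> np.ndarray:
    """Total NE released in each scoring epoch (drive for the sleep model)."""
    out = np.zeros(n_epochs)
    idx = np.floor(events.pulse_onsets_s / epoch_s).astype(int)
    valid = (idx >= 0) & (idx < n_epochs)
    np.add.at(out, idx[valid], np.asarray(ne_amplitudes)[valid])
    return out
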