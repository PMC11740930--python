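"""Whole-mouse and whole-cohort synthesis with ground truth attached.

Each synthetic mouse shares one session clock across its stimulation events,
latent fatigue variables, hypnogram, EEG/EMG, and photometry. Between-mouse
variability enters through multiplicative lognormal jitter on the fatigue
feedback gain and on the unit response amplitudes, emulating differences in
expression level and autoreceptor density across animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..core import Hypnogram, PhotometryTrace, Recording, StimEvents
from .fatigue import FatigueParams, FatigueResult, ne_per_epoch, simulate_fatigue
from .photometry import PhotometrySynthParams, synthesize_photometry
from .protocol import StimProtocol, generate_protocol
from .signals import SignalModelParams, synthesize_eeg_emg
from .sleep import SleepModelParams, simulate_sleep_states

GROUPS = ("control", "kd", "gfp_control")


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort (defaults mirror the reference
    protocol: 24 two-minute episodes at 10-min spacing, 2-s pulses every
    10 +/- 5 s)."""

    protocol: StimProtocol = field(default_factory=StimProtocol)
    fatigue: FatigueParams = field(default_factory=FatigueParams)
    sleep: SleepModelParams = field(default_factory=SleepModelParams)
    signal: SignalModelParams = field(default_factory=SignalModelParams)
    photometry: PhotometrySynthParams | None = None   # None -> sensor preset
    session_length_s: float | None = None             # None -> episodes * spacing
    kd_gamma_factor: float = 0.4   #: feedback multiplier applied in the kd group
    gamma_cv: float = 0.15         #: between-mouse CV of the feedback gain
    amp_cv: float = 0.10           #: between-mouse CV of unit amplitudes

    def resolved_session_length(self) -> float:
        if self.session_length_s is not None:
            return self.session_length_s
        return self.protocol.n_episodes * self.protocol.inter_episode_onset_s


@dataclass
class SyntheticMouse:
    """One simulated animal with full ground truth."""

    mouse_id: str
    group: str
    seed: int
    events: StimEvents
    fatigue_params: FatigueParams           # per-mouse (jittered) parameters
    fatigue: FatigueResult                  # ground-truth C_k, N_k, a(t)
    hypnogram: Hypnogram                    # ground-truth state sequence
    recording: Recording | None = None      # raw EEG/EMG
    photometry: PhotometryTrace | None = None
    sensor: str | None = None               # sensor rendered into `photometry`

    @property
    def true_amplitudes(self) -> np.ndarray:
        """Ground-truth per-pulse amplitudes of the rendered sensor."""
        if self.sensor == "calcium":
            return self.fatigue.calcium
        return self.fatigue.ne


def _jitter(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = float(np.sqrt(np.log(1.0 + cv ** 2)))
    return float(rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma))


def generate_mouse(mouse_id: str, group: str, config: CohortConfig,
                   seed: int, sensor: str = "ne",
                   with_eeg: bool = False,
                   with_photometry: bool = True) -> SyntheticMouse:
    """Simulate one mouse end to end; deterministic given ``seed``.

    ``group`` is one of ``control`` (full autoreceptor feedback), ``kd``
    (feedback gain scaled by ``kd_gamma_factor``), or ``gfp_control``
    (no opsin: stimulation releases no NE and has no effect on sleep).
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    rng = np.random.default_rng(seed)
    session_s = config.resolved_session_length()

    events = generate_protocol(config.protocol, session_s, rng)

    kd = config.kd_gamma_factor if group == "kd" else 1.0
    fp = replace(
        config.fatigue,
        gamma=config.fatigue.gamma * _jitter(rng, config.gamma_cv),
        c0=config.fatigue.c0 * _jitter(rng, config.amp_cv),
        n0=config.fatigue.n0 * _jitter(rng, config.amp_cv),
        kd_factor=kd,
    )
    fat = simulate_fatigue(events, fp)
    if group == "gfp_control":
        fat = FatigueResult(calcium=np.zeros_like(fat.calcium),
                            ne=np.zeros_like(fat.ne),
                            a_pre=np.zeros_like(fat.a_pre),
                            a_post=np.zeros_like(fat.a_post))

    n_epochs = int(round(session_s / 5.0))
    drive = ne_per_epoch(events, fat.ne, n_epochs)
    hyp = simulate_sleep_states(drive, config.sleep, session_s, rng)

    rec = synthesize_eeg_emg(hyp, config.signal, rng) if with_eeg else None

    phot = None
    if with_photometry:
        pp = config.photometry or PhotometrySynthParams.for_sensor(sensor)
        amps = fat.calcium if sensor == "calcium" else fat.ne
        phot = synthesize_photometry(events, amps, pp, session_s, rng,
                                     hypnogram=hyp)
    return SyntheticMouse(mouse_id=mouse_id, group=group, seed=seed,
                          events=events, fatigue_params=fp, fatigue=fat,
                          hypnogram=hyp, recording=rec, photometry=phot,
                          sensor=sensor if with_photometry else None)


def generate_cohort(n_mice: int, config: CohortConfig, seed: int,
                    group: str = "control", sensor: str = "ne",
                    with_eeg: bool = False,
                    with_photometry: bool = True,
                    id_prefix: str = "m") -> list[SyntheticMouse]:
    """Simulate ``n_mice`` independent animals; deterministic given ``seed``."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_mice)]
    return [generate_mouse(f"{id_prefix}{i:02d}", group, config, s,
                           sensor=sensor, with_eeg=with_eeg,
                           with_photometry=with_photometry)
            for i, s in enumerate(seeds)]
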