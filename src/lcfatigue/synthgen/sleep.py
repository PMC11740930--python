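"""Three-state sleep-wake dynamics modulated by NE and rebound pressure.

An epochwise (5-s) Markov chain over {Wake, NREM, REM} whose transition
hazards are modulated by two slow variables:

* ``r_t`` — "recent NE": the NE released in the current epoch plus an
  exponentially decaying trace of past release (time constant tau_h_s / 10).
  It multiplies the NREM->Wake hazard by (1 + ne_wake_gain * r_t),
  capturing the arousing action of noradrenaline.
* ``h_t`` — rebound sleep pressure: integrates recent NE with decay
  constant tau_h_s and multiplies the Wake->NREM hazard by
  (1 + pressure_sleep_gain * h_t), producing rebound sleep after episodes
  of evoked NE release.

Modulated rows are renormalized to sum to 1. With the REM-entry rule set,
REM is reachable only from NREM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import EPOCH_S, Hypnogram


def _default_base_matrix() -> np.ndarray:
    # Rows/cols ordered Wake, NREM, REM; light-phase mouse sleep architecture:
    # wake bouts of a few minutes, NREM-dominated sleep, brief REM from NREM.
    return np.array([
        [0.950, 0.050, 0.000],
        [0.060, 0.920, 0.020],
        [0.100, 0.000, 0.900],
    ])


@dataclass
class SleepModelParams:
    """Parameters of the NE- and pressure-modulated sleep-state chain."""

    base_matrix: np.ndarray = field(default_factory=_default_base_matrix)
    ne_wake_gain: float = 15.0        #: NREM->Wake hazard multiplier per unit recent NE
    alpha_h: float = 0.5              #: pressure increment per unit recent NE
    tau_h_s: float = 150.0            #: pressure decay time constant, seconds
    pressure_sleep_gain: float = 4.0  #: Wake->NREM hazard multiplier per unit pressure
    ne_sleep_suppression: float = 0.0  #: Wake->NREM hazard divisor per unit recent NE
    rem_entry_rule: bool = True       #: REM reachable only from NREM

    def __post_init__(self) -> None:
        self.base_matrix = np.asarray(self.base_matrix, dtype=float)
        if self.base_matrix.shape != (3, 3):
            raise ValueError("base matrix must be 3x3 (Wake, NREM, REM)")
        if np.any(self.base_matrix < 0):
            raise ValueError("base matrix entries must be nonnegative")
        if not np.allclose(self.base_matrix.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("each base matrix row must sum to 1")
        if self.tau_h_s <= 0:
            raise ValueError("tau_h_s must be positive")

    @classmethod
    def sustained(cls, **kwargs) -> "SleepModelParams":
        """Preset emulating arousal populations whose activation holds wake
        probability near 1 for the whole episode: strong NE->wake coupling,
        NE suppression of sleep onset, and no rebound-pressure accumulation."""
        defaults = dict(ne_wake_gain=200.0, ne_sleep_suppression=25.0,
                        alpha_h=0.0)
        defaults.update(kwargs)
        return cls(**defaults)


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 3-state transition matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(np.asarray(matrix, dtype=float).T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = pi / pi.sum()
    if np.any(pi < -1e-9):
        raise ValueError("matrix has no nonnegative stationary distribution")
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def simulate_sleep_states(ne_per_epoch: np.ndarray | None,
                          params: SleepModelParams,
                          session_length_s: float,
                          seed: int | np.random.Generator,
                          initial_state: int | None = None,
                          epoch_s: float = EPOCH_S) -> Hypnogram:
    """Simulate the ground-truth hypnogram for one session.

    Parameters
    ----------
    ne_per_epoch
        NE released per epoch (e.g. from :func:`~lcfatigue.synthgen.fatigue.ne_per_epoch`),
        or None for an unstimulated session.
    session_length_s
        Must divide into whole epochs.
    initial_state
        Starting state code; default: drawn from the base chain's stationary
        distribution.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_epochs = session_length_s / epoch_s
    if abs(n_epochs - round(n_epochs)) > 1e-9:
        raise ValueError("session length must divide into whole epochs")
    n_epochs = int(round(n_epochs))
    ne = np.zeros(n_epochs) if ne_per_epoch is None else np.asarray(ne_per_epoch, float)
    if ne.size != n_epochs:
        raise ValueError("ne_per_epoch length must equal the number of epochs")

    base = params.base_matrix
    pi0 = stationary_distribution(base)
    if initial_state is None:
        state = int(rng.choice(3, p=pi0))
    else:
        state = int(initial_state)

    r_decay = float(np.exp(-epoch_s / (params.tau_h_s / 10.0)))
    h_decay = float(np.exp(-epoch_s / params.tau_h_s))
    trace = 0.0
    h = 0.0
    codes = np.empty(n_epochs, dtype=np.int8)
    # Inverse-CDF sampling from presampled uniforms: one rng stream draw per
    # epoch keeps the run deterministic given the seed and fast in the loop.
    u = rng.random(n_epochs)
    b = [tuple(float(x) for x in base[s]) for s in range(3)]
    ne_list = ne.tolist()
    for i in range(n_epochs):
        trace *= r_decay
        r = ne_list[i] + trace
        trace += ne_list[i]
        h = h * h_decay + params.alpha_h * r
        codes[i] = state

        p0, p1, p2 = b[state]
        if state == 1:  # NREM: NE promotes awakening
            p0 *= 1.0 + params.ne_wake_gain * r
        elif state == 0:  # Wake: pressure promotes sleep onset, NE opposes it
            p1 *= (1.0 + params.pressure_sleep_gain * h) \
                / (1.0 + params.ne_sleep_suppression * r)
            if params.rem_entry_rule:
                p2 = 0.0
        tot = p0 + p1 + p2
        x = u[i] * tot
        state = 0 if x < p0 else (1 if x < p0 + p1 else 2)
    return Hypnogram(codes, epoch_s=epoch_s, t0=0.0)
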