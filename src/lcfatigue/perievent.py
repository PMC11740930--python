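"""Peri-stimulation brain-state analysis.

Computes, around stimulation-episode onsets (or offsets):

* per-mouse sleep-state probability time courses with mouse-level bootstrap
  confidence intervals,
* NREM->Wake and Wake->NREM transition-probability time courses,
* bootstrap significance of a target bin against the -240-0 s baseline,
* the wake-persistence metrics P_peak, P_60, P_60/P_peak and the
  aftereffect P_aft,
* state-restricted EEG delta-power time courses.

All time courses are binned at the 5-s scoring epoch. Probabilities are
computed within mouse (fraction of that mouse's episodes) and then averaged
across mice, matching mouse-level resampling in the bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EPOCH_S, Hypnogram, Recording, STATES
from .staging import compute_epoch_features
from .stats import BootstrapSpec


class BinningError(ValueError):
    pass


def _bin_starts(window: tuple[float, float]) -> np.ndarray:
    w0, w1 = window
    n = (w1 - w0) / EPOCH_S
    if abs(n - round(n)) > 1e-9 or abs(w0 / EPOCH_S - round(w0 / EPOCH_S)) > 1e-9:
        raise BinningError("window must align to 5-s bins")
    return w0 + EPOCH_S * np.arange(int(round(n)))


def _episode_state_matrix(hyp: Hypnogram, align_times: np.ndarray,
                          window: tuple[float, float]) -> np.ndarray:
    """(n_episodes, n_bins) state codes; -1 where the bin falls off-session."""
    starts = _bin_starts(window)
    idx = np.floor((align_times[:, None] + starts[None, :] - hyp.t0)
                   / hyp.epoch_s).astype(int)
    out = np.full(idx.shape, -1, dtype=int)
    ok = (idx >= 0) & (idx < hyp.n_epochs)
    out[ok] = hyp.codes[idx[ok]]
    return out


@dataclass
class StateProbTimecourse:
    """Per-mouse and cohort state-probability time courses."""

    bin_starts: np.ndarray                     #: bin start times rel. to alignment
    per_mouse: dict                            #: mouse -> (n_bins, 3) probabilities
    align: str = "onset"
    ci_low: np.ndarray | None = None           #: (n_bins, 3)
    ci_high: np.ndarray | None = None

    @property
    def mice(self) -> list:
        return list(self.per_mouse)

    @property
    def cohort_mean(self) -> np.ndarray:
        return np.nanmean(np.stack(list(self.per_mouse.values())), axis=0)

    def wake(self, mouse) -> np.ndarray:
        return self.per_mouse[mouse][:, 0]


def state_probability(hypnograms_by_mouse: dict,
                      onsets_by_mouse: dict,
                      window: tuple[float, float] = (-240.0, 360.0),
                      align: str = "onset",
                      episode_duration_s: float = 120.0) -> StateProbTimecourse:
    """Per-mouse probability of each state in each peri-event bin.

    ``align='offset'`` aligns to episode ends (onset + duration). Episodes
    truncated by the session edge contribute only to their in-session bins.
    """
    if align not in ("onset", "offset"):
        raise ValueError("align must be 'onset' or 'offset'")
    if not hypnograms_by_mouse:
        raise ValueError("need at least one mouse")
    starts = _bin_starts(window)
    per_mouse = {}
    for mouse, hyp in hypnograms_by_mouse.items():
        onsets = np.asarray(onsets_by_mouse[mouse], dtype=float)
        if onsets.size == 0:
            raise ValueError(f"mouse {mouse} has no episodes")
        at = onsets + (episode_duration_s if align == "offset" else 0.0)
        sm = _episode_state_matrix(hyp, at, window)
        probs = np.full((starts.size, 3), np.nan)
        valid = sm >= 0
        n_valid = valid.sum(axis=0)
        for s in range(3):
            with np.errstate(invalid="ignore"):
                probs[:, s] = np.where(
                    n_valid > 0, (sm == s).sum(axis=0) / np.maximum(n_valid, 1),
                    np.nan)
        per_mouse[mouse] = probs
    return StateProbTimecourse(bin_starts=starts, per_mouse=per_mouse,
                               align=align)


def bootstrap_state_ci(tc: StateProbTimecourse,
                       spec: BootstrapSpec | None = None) -> StateProbTimecourse:
    """Mouse-level percentile bootstrap CI for the cohort mean, per bin/state.

    Resamples mice with replacement ``B`` times; deterministic given the
    spec's seed. Returns the time course with ``ci_low``/``ci_high`` filled.
    """
    spec = spec or BootstrapSpec()
    x = np.stack(list(tc.per_mouse.values()))          # (n_mice, n_bins, 3)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two mice for a CI")
    rng = np.random.default_rng(spec.seed)
    idx = rng.integers(0, n, size=(spec.B, n))
    boot = np.nanmean(x[idx], axis=1)                  # (B, n_bins, 3)
    alpha = 1 - spec.level
    tc.ci_low = np.percentile(boot, 100 * alpha / 2, axis=0)
    tc.ci_high = np.percentile(boot, 100 * (1 - alpha / 2), axis=0)
    return tc


@dataclass
class TransitionTimecourse:
    """P(source at t-1 -> target at t) per bin, per mouse and cohort."""

    bin_starts: np.ndarray
    pair: tuple[str, str]
    per_mouse: dict                #: mouse -> (n_bins,) with NaN where undefined

    @property
    def cohort_mean(self) -> np.ndarray:
        stacked = np.stack(list(self.per_mouse.values()))
        with np.errstate(invalid="ignore"):
            return np.nanmean(stacked, axis=0)


def transition_timecourse(hypnograms_by_mouse: dict, onsets_by_mouse: dict,
                          pair: tuple[str, str] = ("NREM", "Wake"),
                          window: tuple[float, float] = (-240.0, 360.0),
                          ) -> TransitionTimecourse:
    """Per-bin transition probability for an ordered state pair.

    For each bin t: among this mouse's episodes whose epoch at t-1 (the
    previous 5-s bin) is the source state, the fraction whose epoch at t is
    the target state. Bins with no source-state occupancy are NaN (undefined,
    never zero).
    """
    if pair[0] == pair[1]:
        raise ValueError("source and target states must differ")
    src = STATES.index(pair[0])
    tgt = STATES.index(pair[1])
    starts = _bin_starts(window)
    # include one extra leading bin for the t-1 lookback
    wide = (window[0] - EPOCH_S, window[1])
    per_mouse = {}
    for mouse, hyp in hypnograms_by_mouse.items():
        onsets = np.asarray(onsets_by_mouse[mouse], dtype=float)
        sm = _episode_state_matrix(hyp, onsets, wide)
        prev, cur = sm[:, :-1], sm[:, 1:]
        at_src = (prev == src) & (cur >= 0)
        n_src = at_src.sum(axis=0)
        n_hit = (at_src & (cur == tgt)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            per_mouse[mouse] = np.where(n_src > 0, n_hit / np.maximum(n_src, 1),
                                        np.nan)
    return TransitionTimecourse(bin_starts=starts, pair=(pair[0], pair[1]),
                                per_mouse=per_mouse)


def bootstrap_transition_test(tc: TransitionTimecourse,
                              target_bins: np.ndarray | list,
                              baseline_window: tuple[float, float] = (-240.0, 0.0),
                              spec: BootstrapSpec | None = None) -> dict:
    """Bootstrap significance of target bins against the baseline average.

    Per mouse, d = value at the target bin minus the mouse's mean over
    defined baseline bins. The statistic is the cohort mean of d; the
    two-sided p-value is 2 * min(frac <= 0, frac >= 0) over resampled
    statistics, floored at 1/B. Returns {bin_time: {"p": ..., "observed": ...}}.
    """
    spec = spec or BootstrapSpec()
    starts = tc.bin_starts
    base_sel = (starts >= baseline_window[0]) & (starts < baseline_window[1])
    if not base_sel.any():
        raise ValueError("baseline window contains no bins")
    results = {}
    rng = np.random.default_rng(spec.seed)
    for tb in np.atleast_1d(target_bins):
        j = np.flatnonzero(np.isclose(starts, tb))
        if j.size == 0:
            raise ValueError(f"target bin {tb} not in the window")
        j = int(j[0])
        d = []
        for vals in tc.per_mouse.values():
            base = vals[base_sel]
            if np.all(np.isnan(base)) or np.isnan(vals[j]):
                continue
            d.append(vals[j] - np.nanmean(base))
        d = np.asarray(d)
        if d.size == 0:
            raise ValueError(f"target bin {tb} undefined for every mouse")
        idx = rng.integers(0, d.size, size=(spec.B, d.size))
        boot = d[idx].mean(axis=1)
        frac_le = np.count_nonzero(boot <= 0) / spec.B
        frac_ge = np.count_nonzero(boot >= 0) / spec.B
        p = max(1.0 / spec.B, 2.0 * min(frac_le, frac_ge))
        results[float(tb)] = {"p": float(min(1.0, p)),
                              "observed": float(d.mean()),
                              "n_mice": int(d.size)}
    return results


@dataclass
class WakeMetrics:
    """Wake-persistence and aftereffect metrics for one mouse."""

    baseline_wake_prob: float
    p_peak: float      #: peak increase over baseline within the episode
    p_60: float        #: increase over baseline at the bin containing +60 s
    persistence_ratio: float | None   #: P_60 / P_peak; None when P_peak <= 0
    p_aft: float       #: mean wake prob 0-60 s after episode end, minus baseline


def wake_metrics(tc: StateProbTimecourse, episode_duration_s: float = 120.0,
                 baseline_window: tuple[float, float] = (-240.0, 0.0),
                 t_persist: float = 60.0) -> dict:
    """Per-mouse :class:`WakeMetrics` from an onset-aligned time course."""
    starts = tc.bin_starts
    need_end = episode_duration_s + 60.0
    if starts[0] > baseline_window[0] or starts[-1] + EPOCH_S < need_end:
        raise ValueError("time course must span the baseline through 60 s "
                         "past the episode end")
    base_sel = (starts >= baseline_window[0]) & (starts < baseline_window[1])
    ep_sel = (starts >= 0) & (starts < episode_duration_s)
    aft_sel = (starts >= episode_duration_s) & (starts < episode_duration_s + 60)
    j60 = int(np.flatnonzero((starts <= t_persist)
                             & (t_persist < starts + EPOCH_S))[0])
    out = {}
    for mouse in tc.mice:
        w = tc.wake(mouse)
        base = float(np.nanmean(w[base_sel]))
        p_peak = float(np.nanmax(w[ep_sel]) - base)
        p_60 = float(w[j60] - base)
        # tolerance absorbs float rounding in the baseline mean
        ratio = (p_60 / p_peak) if p_peak > 1e-12 else None
        p_aft = float(np.nanmean(w[aft_sel]) - base)
        out[mouse] = WakeMetrics(baseline_wake_prob=base, p_peak=p_peak,
                                 p_60=p_60, persistence_ratio=ratio,
                                 p_aft=p_aft)
    return out


def cohort_wake_summary(metrics: dict) -> dict:
    """Mean +/- SEM across mice; mice with undefined ratio are excluded from
    the ratio summary and counted."""
    ratios = [m.persistence_ratio for m in metrics.values()
              if m.persistence_ratio is not None]
    afts = [m.p_aft for m in metrics.values()]

    def _ms(vals):
        v = np.asarray(vals, dtype=float)
        sem = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan
        return {"mean": float(v.mean()), "sem": float(sem), "n": int(v.size)}

    return {
        "persistence_ratio": _ms(ratios) if ratios else None,
        "p_aft": _ms(afts),
        "n_ratio_excluded": len(metrics) - len(ratios),
    }


def delta_power_timecourse(recording: Recording, hypnogram: Hypnogram,
                           onsets: np.ndarray,
                           window: tuple[float, float] = (-240.0, 360.0),
                           state: str = "NREM",
                           baseline_window: tuple[float, float] = (-240.0, 0.0),
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Peri-event EEG delta power restricted to epochs in ``state``.

    Per bin: mean epoch delta power over episodes whose epoch is in the
    chosen state, normalized by the session's mean delta power over
    baseline-window epochs in that state (pooled over episodes). Bins where
    the state never occurs are NaN.
    """
    s = STATES.index(state)
    feats = compute_epoch_features(recording)
    starts = _bin_starts(window)
    onsets = np.asarray(onsets, dtype=float)
    idx = np.floor((onsets[:, None] + starts[None, :] - hypnogram.t0)
                   / hypnogram.epoch_s).astype(int)
    ok = (idx >= 0) & (idx < min(hypnogram.n_epochs, feats.n_epochs))
    in_state = np.zeros_like(ok)
    power = np.zeros(idx.shape)
    in_state[ok] = hypnogram.codes[idx[ok]] == s
    power[ok] = feats.delta_power[np.clip(idx, 0, feats.n_epochs - 1)][ok]

    base_sel = (starts >= baseline_window[0]) & (starts < baseline_window[1])
    base_vals = power[:, base_sel][in_state[:, base_sel]]
    if base_vals.size == 0:
        raise ValueError(f"state {state} absent from the baseline window")
    base = float(base_vals.mean())

    n_state = in_state.sum(axis=0)
    with np.errstate(invalid="ignore"):
        course = np.where(n_state > 0,
                          np.where(in_state, power, 0.0).sum(axis=0)
                          / np.maximum(n_state, 1) / base,
                          np.nan)
    return starts, course
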