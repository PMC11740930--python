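"""Per-pulse evoked-response quantification and fatigue statistics.

A pulse's response amplitude is the mean corrected signal over [onset,
onset + 1 s) minus the mean over [onset - 1.5 s, onset). Amplitudes are
averaged per pulse index across a session's episodes; the averaged profile
is normalized by its own maximum for display and group comparison; the
fatigue ratio is the episode-averaged raw amplitude at pulse k (default 12)
over pulse 1. Windows are half-open in session seconds, with photometry
samples assigned by timestamp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CorrectedTrace, StimEvents
from .stats import rank_sum, scheirer_ray_hare, SRHResult

RESPONSE_WINDOW = (0.0, 1.0)
BASELINE_WINDOW = (-1.5, 0.0)


@dataclass
class PulseAmplitudes:
    """Per-episode x pulse-index amplitude matrix (NaN where dropped)."""

    amplitudes: np.ndarray        #: (n_episodes, max_pulses), NaN padded
    n_dropped_masked: int         #: pulses dropped for artifact overlap
    drop_reasons: list = field(default_factory=list)


def pulse_amplitudes(corrected: CorrectedTrace, events: StimEvents,
                     mask_drop_fraction: float = 0.5) -> PulseAmplitudes:
    """Baseline-subtracted response amplitude for every pulse.

    Pulses whose response or baseline window overlaps masked artifact
    samples beyond ``mask_drop_fraction`` are dropped (NaN) and counted.
    """
    t = corrected.t
    z = corrected.z
    mask = corrected.artifact_mask
    t0, dt = t[0], t[1] - t[0]

    per_episode = [events.pulse_onsets_s[events.episode_index_per_pulse == ep]
                   for ep in range(events.n_episodes)]
    max_pulses = max(len(p) for p in per_episode)
    out = np.full((events.n_episodes, max_pulses), np.nan)
    n_dropped = 0
    reasons = []
    n = t.size
    for ep, onsets in enumerate(per_episode):
        for k, onset in enumerate(onsets):
            i_r0 = int(np.ceil((onset + RESPONSE_WINDOW[0] - t0) / dt - 1e-9))
            i_r1 = int(np.ceil((onset + RESPONSE_WINDOW[1] - t0) / dt - 1e-9))
            i_b0 = int(np.ceil((onset + BASELINE_WINDOW[0] - t0) / dt - 1e-9))
            i_b1 = i_r0
            if i_b0 < 0 or i_r1 > n:
                n_dropped += 1
                reasons.append((ep, k + 1, "window outside trace"))
                continue
            resp_m = mask[i_r0:i_r1]
            base_m = mask[i_b0:i_b1]
            if resp_m.size == 0 or base_m.size == 0 or \
                    resp_m.mean() > mask_drop_fraction or \
                    base_m.mean() > mask_drop_fraction:
                n_dropped += 1
                reasons.append((ep, k + 1, "masked beyond threshold"))
                continue
            out[ep, k] = z[i_r0:i_r1].mean() - z[i_b0:i_b1].mean()
    return PulseAmplitudes(amplitudes=out, n_dropped_masked=n_dropped,
                           drop_reasons=reasons)


@dataclass
class PulseResponseSet:
    """Episode-averaged per-pulse-index responses and their normalized profile."""

    mean_amplitude: np.ndarray    #: per pulse index (1-based index k -> [k-1])
    norm_amplitude: np.ndarray    #: mean / max(mean)
    n_episodes: np.ndarray        #: episodes contributing per index


def average_and_normalize(amps: PulseAmplitudes | np.ndarray) -> PulseResponseSet:
    """Average amplitudes across episodes per pulse index; normalize by the
    maximum of the averaged profile. Indices beyond the shortest episode are
    averaged over the episodes that contain them."""
    a = amps.amplitudes if isinstance(amps, PulseAmplitudes) else np.asarray(amps, float)
    if a.ndim == 1:
        a = a[None, :]
    if a.shape[1] < 2:
        raise ValueError("need at least two pulses per episode")
    n_contrib = np.sum(np.isfinite(a), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_contrib > 0, np.nansum(a, axis=0)
                        / np.maximum(n_contrib, 1), np.nan)
    peak = np.nanmax(mean)
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("all pulse-index averages nonpositive: "
                         "normalization undefined")
    return PulseResponseSet(mean_amplitude=mean, norm_amplitude=mean / peak,
                            n_episodes=n_contrib)


@dataclass
class FatigueRatio:
    ratio: float | None
    k: int
    n_episodes_1: int
    n_episodes_k: int
    reason: str | None = None


def fatigue_ratio(prs: PulseResponseSet, k: int = 12,
                  min_episodes: int = 3) -> FatigueRatio:
    """Episode-averaged raw amplitude at pulse ``k`` over pulse 1.

    Undefined (with a reason) when pulse 1's average is nonpositive or when
    fewer than ``min_episodes`` episodes contribute to either index.
    """
    if k < 2 or k > prs.mean_amplitude.size:
        raise ValueError(f"pulse index {k} outside the available profile")
    n1 = int(prs.n_episodes[0])
    nk = int(prs.n_episodes[k - 1])
    if n1 < min_episodes or nk < min_episodes:
        return FatigueRatio(None, k, n1, nk, reason="too few episodes")
    a1 = prs.mean_amplitude[0]
    ak = prs.mean_amplitude[k - 1]
    if not np.isfinite(a1) or a1 <= 0:
        return FatigueRatio(None, k, n1, nk, reason="pulse-1 average <= 0")
    return FatigueRatio(float(ak / a1), k, n1, nk)


def cohort_ratio_summary(ratios: list) -> dict:
    """Mean +/- SEM of defined per-mouse ratios, with exclusion count."""
    vals = np.array([r.ratio for r in ratios if r.ratio is not None])
    n_exc = sum(1 for r in ratios if r.ratio is None)
    if vals.size == 0:
        return {"mean": None, "sem": None, "n": 0, "n_excluded": n_exc}
    sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
    return {"mean": float(vals.mean()), "sem": float(sem),
            "n": int(vals.size), "n_excluded": n_exc}


def compare_fatigue_groups(ratios_a, ratios_b,
                           sided: str = "two-sided") -> tuple[float, float, dict]:
    """Wilcoxon rank-sum on per-mouse fatigue ratios (exact for small groups).

    ``sided='less'`` tests the alternative that group A's ratios are smaller
    (stronger fatigue) than group B's.
    """
    a = [r.ratio if hasattr(r, "ratio") else float(r) for r in ratios_a]
    b = [r.ratio if hasattr(r, "ratio") else float(r) for r in ratios_b]
    a = [v for v in a if v is not None]
    b = [v for v in b if v is not None]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 mice with defined ratios")
    return rank_sum(a, b, sided=sided)


def compare_profiles_srh(profiles_by_group: dict) -> SRHResult:
    """Scheirer-Ray-Hare test on normalized per-pulse profiles.

    ``profiles_by_group`` maps group label -> (n_mice, n_pulse_indices)
    array of normalized responses (one row per mouse). Factors are group
    and pulse index; H and p for both main effects and the interaction are
    returned, with flags for unbalanced or incomplete designs.
    """
    values, fa, fb = [], [], []
    for group, mat in profiles_by_group.items():
        mat = np.asarray(mat, dtype=float)
        for row in mat:
            for j, v in enumerate(row):
                if np.isfinite(v):
                    values.append(v)
                    fa.append(group)
                    fb.append(j + 1)
    return scheirer_ray_hare(np.array(values), np.array(fa), np.array(fb))
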