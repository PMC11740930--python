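"""Reference cohort-level experiments.

Each function builds synthetic cohorts with the generator, runs the relevant
analysis chain end to end, and returns summary numbers. They serve as the
package's self-validation studies (round-trip label recovery, amplitude
recovery, regime contrast, detection power, test calibration) and are what
``scripts/acceptance.py`` executes.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .perievent import (bootstrap_transition_test, cohort_wake_summary,
                        state_probability, transition_timecourse, wake_metrics)
from .photoproc import preprocess
from .pulses import average_and_normalize, fatigue_ratio, pulse_amplitudes
from .staging import stage_recording
from .stats import BootstrapSpec, rank_sum
from .synthgen import (CohortConfig, FatigueParams, PhotometrySynthParams, StimProtocol,
                       SignalModelParams, SleepModelParams,
                       generate_cohort, generate_mouse, simulate_sleep_states,
                       synthesize_eeg_emg)


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------


def staging_round_trip(n_mice: int = 4, session_s: float = 3600.0,
                       seed: int = 0) -> dict:
    """Synthesize EEG/EMG from known hypnograms, restage with auto
    thresholds, and score label recovery."""
    correct = total = 0
    state_hits = np.zeros(3)
    state_counts = np.zeros(3)
    for s in _seeds(seed, n_mice):
        rng = np.random.default_rng(s)
        hyp = simulate_sleep_states(None, SleepModelParams(), session_s, rng)
        rec = synthesize_eeg_emg(hyp, SignalModelParams(), rng)
        est, _ = stage_recording(rec)
        correct += int((est.codes == hyp.codes).sum())
        total += hyp.n_epochs
        for st in range(3):
            sel = hyp.codes == st
            state_counts[st] += sel.sum()
            state_hits[st] += (est.codes[sel] == st).sum()
    recalls = state_hits / np.maximum(state_counts, 1)
    return {"accuracy": correct / total,
            "recall_wake": float(recalls[0]),
            "recall_nrem": float(recalls[1]),
            "recall_rem": float(recalls[2]),
            "n_epochs": int(total)}


# ---------------------------------------------------------------------------


def _true_amplitude_matrix(mouse) -> np.ndarray:
    ev = mouse.events
    n_idx = max(np.sum(ev.episode_index_per_pulse == ep)
                for ep in range(ev.n_episodes))
    out = np.full((ev.n_episodes, n_idx), np.nan)
    for ep in range(ev.n_episodes):
        sel = ev.episode_index_per_pulse == ep
        out[ep, :sel.sum()] = mouse.true_amplitudes[sel]
    return out


def photometry_round_trip(seed: int = 0, sensor: str = "ne",
                          corruption: str = "default") -> dict:
    """Synthesize one session's photometry, run the correction chain, and
    compare episode-averaged per-pulse-index amplitudes with ground truth.

    ``corruption='none'`` turns off bleach, artifacts, noise and the
    state-dependent baseline; the chain then recovers per-pulse amplitudes
    exactly up to an affine map.
    """
    kwargs = {}
    k_mad = 8.0
    cfg = CohortConfig()
    if corruption == "none":
        kwargs = dict(noise_sd=0.0, artifact_amp=0.0,
                      state_baseline={"Wake": 0.0, "NREM": 0.0, "REM": 0.0},
                      bleach_470=(0.0, 1000.0, 0.0, 2000.0, 100.0),
                      bleach_405=(0.0, 1000.0, 0.0, 2000.0, 80.0))
        k_mad = np.inf
        # jitter-free spacing beyond the kernel support keeps every
        # baseline window clean, so recovery is affine-exact
        cfg = CohortConfig(
            protocol=StimProtocol(inter_pulse_mean_s=12.0,
                                  inter_pulse_jitter_s=0.0))
    pp = PhotometrySynthParams.for_sensor(sensor, **kwargs)
    cfg = replace(cfg, photometry=pp)
    m = generate_mouse("m0", "control", cfg, seed, sensor=sensor)
    ct = preprocess(m.photometry, k_mad=k_mad)
    amps = pulse_amplitudes(ct, m.events)
    est = amps.amplitudes
    true = _true_amplitude_matrix(m)

    prs = average_and_normalize(amps)
    n_idx = est.shape[1]
    true_mean = np.array([np.nanmean(true[:, j][np.isfinite(est[:, j])])
                          for j in range(n_idx)])
    good = prs.n_episodes >= 3
    r_profile = float(np.corrcoef(prs.mean_amplitude[good],
                                  true_mean[good])[0, 1])

    ok = np.isfinite(est) & np.isfinite(true)
    r_pulse = float(np.corrcoef(est[ok], true[ok])[0, 1])
    # residual of the best affine map truth -> estimate, per pulse
    A = np.vstack([true[ok], np.ones(ok.sum())]).T
    coef, *_ = np.linalg.lstsq(A, est[ok], rcond=None)
    resid = est[ok] - A @ coef
    rel_affine_resid = float(np.sqrt(np.mean(resid ** 2))
                             / np.std(est[ok]))
    return {"r_profile": r_profile, "r_pulse": r_pulse,
            "rel_affine_resid": rel_affine_resid,
            "n_pulses": int(ok.sum())}


# ---------------------------------------------------------------------------


def _cohort_metrics(config: CohortConfig, n_mice: int, seed: int) -> dict:
    mice = generate_cohort(n_mice, config, seed, with_photometry=False)
    hyps = {m.mouse_id: m.hypnogram for m in mice}
    ons = {m.mouse_id: m.events.episode_onsets_s for m in mice}
    tc = state_probability(hyps, ons,
                           episode_duration_s=config.protocol.episode_duration_s)
    return cohort_wake_summary(
        wake_metrics(tc, episode_duration_s=config.protocol.episode_duration_s))


def regime_contrast(n_mice: int = 8, seed: int = 0) -> dict:
    """Transient regime (fatigue on, rebound pressure on) versus sustained
    regime (fatigue off, NE maintains wakefulness, no pressure)."""
    transient = _cohort_metrics(CohortConfig(), n_mice, seed)
    sustained_cfg = CohortConfig(
        fatigue=replace(FatigueParams(), gamma=0.0),
        sleep=SleepModelParams.sustained(),
    )
    sustained = _cohort_metrics(sustained_cfg, n_mice, seed + 1)
    return {
        "transient_ratio": transient["persistence_ratio"]["mean"],
        "transient_p_aft": transient["p_aft"]["mean"],
        "sustained_ratio": sustained["persistence_ratio"]["mean"],
        "sustained_p_aft": sustained["p_aft"]["mean"],
    }


# ---------------------------------------------------------------------------


def estimate_mouse_ratio(mouse, k: int = 12, k_mad: float = 8.0):
    """Full-chain per-mouse fatigue ratio from raw synthetic photometry."""
    ct = preprocess(mouse.photometry, k_mad=k_mad)
    amps = pulse_amplitudes(ct, mouse.events)
    return fatigue_ratio(average_and_normalize(amps), k=k)


def true_mouse_ratio(mouse, k: int = 12) -> float:
    true = _true_amplitude_matrix(mouse)
    return float(np.nanmean(true[:, k - 1]) / np.nanmean(true[:, 0]))


def fatigue_ratio_recovery(n_mice: int = 6, seed: int = 0) -> dict:
    """Estimated pulse-12/pulse-1 ratios versus ground truth, per sensor."""
    out = {}
    for sensor in ("calcium", "ne"):
        cfg = CohortConfig()
        mice = generate_cohort(n_mice, cfg, seed, sensor=sensor)
        est, true = [], []
        for m in mice:
            fr = estimate_mouse_ratio(m)
            if fr.ratio is None:
                continue
            est.append(fr.ratio)
            true.append(true_mouse_ratio(m))
        est, true = np.asarray(est), np.asarray(true)
        out[sensor] = {
            "estimated_mean": float(est.mean()),
            "true_mean": float(true.mean()),
            "max_abs_error": float(np.abs(est - true).max()),
            "mean_abs_error": float(np.abs(est - true).mean()),
            "n": int(est.size),
        }
    out["ordering_preserved"] = bool(
        out["ne"]["estimated_mean"] < out["calcium"]["estimated_mean"])
    return out


# ---------------------------------------------------------------------------


def knockdown_power(n_replicates: int = 50, n_per_group: int = 8,
                    seed: int = 0, alpha: float = 0.05) -> dict:
    """Fraction of replicate cohorts where the one-sided rank-sum test
    detects weaker fatigue (larger NE ratio) in the knockdown group."""
    cfg = CohortConfig()
    hits = 0
    for rep_seed in _seeds(seed, n_replicates):
        sub = _seeds(rep_seed, 2)
        ctrl = generate_cohort(n_per_group, cfg, sub[0], group="control",
                               sensor="ne", id_prefix="c")
        kd = generate_cohort(n_per_group, cfg, sub[1], group="kd",
                             sensor="ne", id_prefix="k")
        r_ctrl = [estimate_mouse_ratio(m).ratio for m in ctrl]
        r_kd = [estimate_mouse_ratio(m).ratio for m in kd]
        r_ctrl = [r for r in r_ctrl if r is not None]
        r_kd = [r for r in r_kd if r is not None]
        # alternative: control fatigues more -> control ratios smaller
        _, p, _ = rank_sum(r_ctrl, r_kd, sided="less")
        hits += p < alpha
    return {"power": hits / n_replicates, "n_replicates": n_replicates,
            "n_per_group": n_per_group, "alpha": alpha}


# ---------------------------------------------------------------------------


def transition_test_type1(n_cohorts: int = 400, n_mice: int = 8,
                          seed: int = 0, B: int = 10_000,
                          alpha: float = 0.05) -> dict:
    """Type-I error of the bootstrap transition test under the generator's
    no-stimulation-effect setting (NREM->Wake at the onset bin versus the
    -240-0 s baseline)."""
    cfg = CohortConfig(sleep=SleepModelParams(ne_wake_gain=0.0, alpha_h=0.0))
    rejections = 0
    for i, cseed in enumerate(_seeds(seed, n_cohorts)):
        mice = generate_cohort(n_mice, cfg, cseed, group="gfp_control",
                               with_photometry=False)
        hyps = {m.mouse_id: m.hypnogram for m in mice}
        ons = {m.mouse_id: m.events.episode_onsets_s for m in mice}
        tc = transition_timecourse(hyps, ons, pair=("NREM", "Wake"),
                                   window=(-240.0, 60.0))
        res = bootstrap_transition_test(
            tc, [0.0], spec=BootstrapSpec(B=B, seed=cseed))
        rejections += res[0.0]["p"] < alpha
    return {"type1_rate": rejections / n_cohorts, "n_cohorts": n_cohorts,
            "alpha": alpha, "B": B}
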