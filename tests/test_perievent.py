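"""Peri-event time courses: hand-counted probabilities, transition
definitions, bootstrap enumeration, wake metrics, delta-power normalization."""

import itertools

import numpy as np
import pytest

from lcfatigue.core import Hypnogram, Recording
from lcfatigue.perievent import (StateProbTimecourse, bootstrap_state_ci,
                                 bootstrap_transition_test,
                                 cohort_wake_summary, delta_power_timecourse,
                                 state_probability, transition_timecourse,
                                 wake_metrics)
from lcfatigue.stats import BootstrapSpec

W = (-20.0, 20.0)   # small window: 8 bins


def _hyp(labels):
    return Hypnogram.from_labels(labels)


def test_all_wake_hypnogram_gives_probability_one():
    hyp = _hyp(["Wake"] * 200)
    tc = state_probability({"m1": hyp}, {"m1": [300.0]}, window=W)
    assert np.allclose(tc.per_mouse["m1"][:, 0], 1.0)
    assert np.allclose(tc.per_mouse["m1"].sum(axis=1), 1.0)


def test_probability_is_fraction_of_episodes():
    """Two episodes, Wake at one bin for exactly one of them -> P=0.5."""
    labels = ["NREM"] * 200
    labels[60] = "Wake"            # epoch 60 -> t = 300 s
    hyp = _hyp(labels)
    tc = state_probability({"m1": hyp}, {"m1": [300.0, 600.0]}, window=W)
    j = np.flatnonzero(tc.bin_starts == 0.0)[0]
    assert tc.per_mouse["m1"][j, 0] == 0.5
    assert tc.per_mouse["m1"][j, 1] == 0.5


def test_probabilities_sum_to_one_per_bin(rng):
    labels = [("Wake", "NREM", "REM")[i] for i in rng.integers(0, 3, 500)]
    tc = state_probability({"m": _hyp(labels)}, {"m": [600.0, 1200.0]},
                           window=(-240.0, 360.0))
    assert np.allclose(tc.per_mouse["m"].sum(axis=1), 1.0)


def test_truncated_episode_excluded_from_missing_bins_only():
    hyp = _hyp(["Wake"] * 100)     # 500-s session
    tc = state_probability({"m": _hyp(["Wake"] * 100)}, {"m": [10.0]},
                           window=W)
    probs = tc.per_mouse["m"]
    assert np.isnan(probs[0, 0])        # bin at -20 s precedes the session
    assert probs[-1, 0] == 1.0


def test_offset_alignment_matches_paft_numerator():
    labels = ["NREM"] * 100
    hyp = _hyp(labels)
    on = state_probability({"m": hyp}, {"m": [120.0]}, window=(120.0, 180.0),
                           align="onset")
    off = state_probability({"m": hyp}, {"m": [120.0]}, window=(0.0, 60.0),
                            align="offset", episode_duration_s=120.0)
    assert np.allclose(on.per_mouse["m"], off.per_mouse["m"])


class TestTransitions:
    def test_hand_counted_switch(self):
        """Deterministic NREM,NREM,Wake,Wake pattern (20-s period), episodes
        aligned to its phase: NREM->Wake is 1 exactly where the previous
        epoch is the second NREM (relative times -10 and +10 s here), 0 at
        the other NREM-sourced bins, undefined where the source is Wake."""
        labels = (["NREM", "NREM", "Wake", "Wake"] * 100)[:400]
        onsets = [200.0, 600.0, 1000.0, 1400.0]   # all at pattern phase 0
        tc = transition_timecourse({"m": _hyp(labels)}, {"m": onsets},
                                   pair=("NREM", "Wake"), window=W)
        vals = tc.per_mouse["m"]
        phase = np.mod(tc.bin_starts / 5.0, 4).astype(int)
        assert np.all(vals[phase == 2] == 1.0)    # prev epoch: second NREM
        assert np.all(vals[phase == 1] == 0.0)    # prev epoch: first NREM
        assert np.all(np.isnan(vals[(phase == 0) | (phase == 3)]))

    def test_absent_source_state_is_undefined_not_zero(self):
        hyp = _hyp(["NREM"] * 200)
        tc = transition_timecourse({"m": hyp}, {"m": [300.0]},
                                   pair=("NREM", "Wake"), window=W)
        assert np.all(tc.per_mouse["m"] == 0.0)
        tc2 = transition_timecourse({"m": hyp}, {"m": [300.0]},
                                    pair=("Wake", "NREM"), window=W)
        assert np.all(np.isnan(tc2.per_mouse["m"]))

    def test_invariant_to_duplicating_episodes(self, rng):
        labels = [("Wake", "NREM", "REM")[i] for i in rng.integers(0, 3, 400)]
        hyp = _hyp(labels)
        a = transition_timecourse({"m": hyp}, {"m": [600.0, 1200.0]}, window=W)
        b = transition_timecourse({"m": hyp},
                                  {"m": [600.0, 1200.0, 600.0, 1200.0]},
                                  window=W)
        assert np.allclose(a.per_mouse["m"], b.per_mouse["m"], equal_nan=True)

    def test_identical_pair_rejected(self):
        with pytest.raises(ValueError):
            transition_timecourse({}, {}, pair=("Wake", "Wake"), window=W)


class TestBootstrap:
    def test_identical_mice_give_zero_width_ci(self):
        probs = np.tile([[0.5, 0.5, 0.0]], (8, 1))
        tc = StateProbTimecourse(bin_starts=np.array([0.0]),
                                 per_mouse={f"m{i}": probs[i][None, :]
                                            for i in range(8)})
        tc = bootstrap_state_ci(tc, BootstrapSpec(B=500, seed=0))
        assert np.allclose(tc.ci_low, tc.ci_high)

    def test_two_mouse_ci_matches_exhaustive_enumeration(self):
        """Mice with P(Wake) = 0 and 1: the bootstrap distribution has
        support {0, 0.5, 1} with probabilities {1/4, 1/2, 1/4}; the MC
        percentile CI must match the enumerated distribution's quantiles."""
        tc = StateProbTimecourse(
            bin_starts=np.array([0.0]),
            per_mouse={"a": np.array([[0.0, 1.0, 0.0]]),
                       "b": np.array([[1.0, 0.0, 0.0]])})
        tc = bootstrap_state_ci(tc, BootstrapSpec(B=20000, seed=1))
        enum = np.array([np.mean(pick) for pick in
                         itertools.product([0.0, 1.0], repeat=2)])
        lo, hi = np.quantile(enum, [0.025, 0.975], method="inverted_cdf")
        assert tc.ci_low[0, 0] == pytest.approx(lo, abs=0.02)
        assert tc.ci_high[0, 0] == pytest.approx(hi, abs=0.02)

    def test_null_target_bin_gives_large_p(self):
        starts = np.arange(-240.0, 60.0, 5.0)
        vals = {f"m{i}": np.full(starts.size, 0.3 + 0.01 * i)
                for i in range(6)}
        from lcfatigue.perievent import TransitionTimecourse
        tc = TransitionTimecourse(bin_starts=starts, pair=("NREM", "Wake"),
                                  per_mouse=vals)
        res = bootstrap_transition_test(tc, [0.0],
                                        spec=BootstrapSpec(B=2000, seed=0))
        assert res[0.0]["p"] > 0.5

    def test_extreme_separation_hits_p_floor(self):
        starts = np.arange(-240.0, 60.0, 5.0)
        per_mouse = {}
        rng = np.random.default_rng(0)
        for i in range(8):
            v = np.full(starts.size, 0.2 + 0.001 * rng.standard_normal())
            v[starts == 0.0] = 0.9 + 0.001 * i
            per_mouse[f"m{i}"] = v
        from lcfatigue.perievent import TransitionTimecourse
        tc = TransitionTimecourse(bin_starts=starts, pair=("NREM", "Wake"),
                                  per_mouse=per_mouse)
        spec = BootstrapSpec(B=1000, seed=0)
        res = bootstrap_transition_test(tc, [0.0], spec=spec)
        assert res[0.0]["p"] == pytest.approx(1.0 / spec.B)


class TestWakeMetrics:
    def _course(self, baseline, peak, at60, aft):
        starts = np.arange(-240.0, 240.0, 5.0)
        wake = np.full(starts.size, baseline)
        wake[starts == 30.0] = peak
        wake[starts == 60.0] = at60
        wake[(starts >= 120.0) & (starts < 180.0)] = aft
        probs = np.zeros((starts.size, 3))
        probs[:, 0] = wake
        probs[:, 1] = 1 - wake
        return StateProbTimecourse(bin_starts=starts, per_mouse={"m": probs})

    def test_hand_constructed_course(self):
        """Baseline 0.40, peak 1.00, 0.55 at +60 s, post-episode mean 0.40
        -> P_peak 0.60, P_60 0.15, ratio 0.25, P_aft 0.00, exactly."""
        tc = self._course(0.40, 1.00, 0.55, 0.40)
        m = wake_metrics(tc, episode_duration_s=120.0)["m"]
        assert m.p_peak == pytest.approx(0.60, abs=1e-12)
        assert m.p_60 == pytest.approx(0.15, abs=1e-12)
        assert m.persistence_ratio == pytest.approx(0.25, abs=1e-12)
        assert m.p_aft == pytest.approx(0.0, abs=1e-12)

    def test_flat_course_has_undefined_ratio(self):
        tc = self._course(0.4, 0.4, 0.4, 0.4)
        m = wake_metrics(tc, episode_duration_s=120.0)["m"]
        assert m.p_peak == pytest.approx(0.0, abs=1e-12)
        assert m.persistence_ratio is None
        assert m.p_aft == pytest.approx(0.0, abs=1e-12)
        summary = cohort_wake_summary({"m": m})
        assert summary["persistence_ratio"] is None
        assert summary["n_ratio_excluded"] == 1

    def test_sustained_square_response(self):
        starts = np.arange(-240.0, 240.0, 5.0)
        wake = np.where(starts < 0, 0.4, 1.0)
        probs = np.zeros((starts.size, 3))
        probs[:, 0] = wake
        probs[:, 1] = 1 - wake
        tc = StateProbTimecourse(bin_starts=starts, per_mouse={"m": probs})
        m = wake_metrics(tc, episode_duration_s=120.0)["m"]
        assert m.persistence_ratio == pytest.approx(1.0)
        assert m.p_aft == pytest.approx(0.6)


class TestDeltaPower:
    def _stationary_recording(self, rng, n_epochs=240, fs=100.0):
        n = int(n_epochs * 5 * fs)
        from scipy import signal as sps
        sos = sps.butter(4, (1.0, 5.0), btype="bandpass", fs=fs, output="sos")
        eeg = sps.sosfiltfilt(sos, rng.standard_normal(n))
        return Recording(eeg=eeg, emg=np.zeros(n), fs=fs)

    def test_stationary_eeg_normalizes_to_one(self, rng):
        rec = self._stationary_recording(rng)
        hyp = Hypnogram(np.ones(240, dtype=int))
        _, course = delta_power_timecourse(rec, hyp, [400.0, 800.0],
                                           window=(-240.0, 240.0))
        assert np.nanmean(course) == pytest.approx(1.0, abs=0.1)

    def test_gain_invariance_and_power_scaling(self, rng):
        rec = self._stationary_recording(rng)
        hyp = Hypnogram(np.ones(240, dtype=int))
        _, base = delta_power_timecourse(rec, hyp, [400.0],
                                         window=(-240.0, 240.0))
        rec2 = Recording(eeg=3.0 * rec.eeg, emg=rec.emg, fs=rec.fs)
        _, scaled = delta_power_timecourse(rec2, hyp, [400.0],
                                           window=(-240.0, 240.0))
        assert np.allclose(base, scaled, equal_nan=True, rtol=1e-9)
        # doubling delta amplitude after the episode quadruples the
        # normalized course there
        eeg = rec.eeg.copy()
        cut = int(520.0 * rec.fs)
        eeg[cut:] *= 2.0
        rec4 = Recording(eeg=eeg, emg=rec.emg, fs=rec.fs)
        _, c4 = delta_power_timecourse(rec4, hyp, [400.0],
                                       window=(-240.0, 240.0))
        sel = _bins_after = slice(None)
        starts = np.arange(-240.0, 240.0, 5.0)
        post = starts >= 125.0
        assert np.nanmean(c4[post]) == pytest.approx(4.0, rel=0.15)

    def test_absent_state_raises(self, rng):
        rec = self._stationary_recording(rng)
        hyp = Hypnogram(np.zeros(240, dtype=int))   # all Wake
        with pytest.raises(ValueError):
            delta_power_timecourse(rec, hyp, [400.0], window=(-240.0, 240.0),
                                   state="NREM")
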