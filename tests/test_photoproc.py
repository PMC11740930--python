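"""Photometry correction chain: bleach fitting, isosbestic regression,
z-scoring, the display low-pass, artifact removal, and chain invariances."""

import numpy as np
import pytest

from lcfatigue.core import PhotometryTrace
from lcfatigue.photoproc import (fit_bleach, isosbestic_correct, lowpass_02hz,
                                 preprocess, remove_artifacts, zscore)

FS = 10.0


def _t(minutes=40.0):
    return np.arange(int(minutes * 60 * FS)) / FS


def _biexp(t, a1, tau1, a2, tau2, c):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


class TestBleachFit:
    def test_recovers_generated_curve_within_one_percent(self):
        t = _t()
        y = _biexp(t, 100.0, 1800.0, 20.0, 300.0, 5.0)
        fit, det = fit_bleach(t, y)
        taus = sorted([fit.tau1_s, fit.tau2_s])
        amps = [fit.A1, fit.A2] if fit.tau1_s < fit.tau2_s else [fit.A2, fit.A1]
        assert taus[0] == pytest.approx(300.0, rel=0.01)
        assert taus[1] == pytest.approx(1800.0, rel=0.01)
        assert amps[0] == pytest.approx(20.0, rel=0.01)
        assert amps[1] == pytest.approx(100.0, rel=0.01)
        assert fit.offset == pytest.approx(5.0, rel=0.01)
        assert fit.residual_rms < 1e-4 * 120.0

    def test_constant_input_detrends_to_zero(self):
        t = _t(15.0)
        fit, det = fit_bleach(t, np.full(t.size, 42.0))
        assert np.allclose(det, 0.0, atol=1e-6)

    def test_residual_rms_tracks_noise_floor(self, rng):
        t = _t()
        y = _biexp(t, 100.0, 1800.0, 20.0, 300.0, 5.0) + rng.standard_normal(t.size)
        fit, det = fit_bleach(t, y)
        assert fit.residual_rms == pytest.approx(1.0, rel=0.2)

    def test_short_trace_rejected(self):
        t = _t(5.0)
        with pytest.raises(ValueError):
            fit_bleach(t, np.ones(t.size))


class TestIsosbestic:
    def test_perfect_shared_component_cancels(self, rng):
        m = rng.standard_normal(6000)
        corrected, info = isosbestic_correct(2.0 * m, m)
        assert np.allclose(corrected, 0.0, atol=1e-9)
        assert info["slope"] == pytest.approx(2.0)

    def test_orthogonal_signal_survives_correction(self):
        """det470 = s + 0.7 m with s orthogonal to m: the regression removes
        m and leaves s (residual artifact power < 1% of m's power)."""
        n = 6000
        t = np.arange(n)
        s = np.sin(2 * np.pi * t / 500.0)
        m = np.sin(2 * np.pi * t / 333.0)   # orthogonal-ish distinct harmonic
        s -= s.mean()
        m -= m.mean()
        m -= (m @ s) / (s @ s) * s           # enforce exact orthogonality
        corrected, _ = isosbestic_correct(s + 0.7 * m, m)
        resid = corrected - s
        assert np.sum(resid ** 2) < 0.01 * np.sum(m ** 2)

    def test_constant_isosbestic_degrades_to_centering(self):
        y = np.arange(100, dtype=float)
        corrected, info = isosbestic_correct(y, np.zeros(100))
        assert info["degenerate_isosbestic"]
        assert np.allclose(corrected, y - y.mean())


class TestZScore:
    def test_three_point_example(self):
        z, info = zscore(np.array([1.0, 2.0, 3.0]))
        assert np.allclose(z, [-1.0, 0.0, 1.0])   # ddof=1 convention
        assert info["ddof"] == 1

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(500)
        z1, _ = zscore(x)
        z2, _ = zscore(5.0 * x - 3.0)
        assert np.allclose(z1, z2)

    def test_masked_samples_excluded_from_moments(self):
        x = np.array([1.0, 2.0, 3.0, 100.0])
        mask = np.array([False, False, False, True])
        z, _ = zscore(x, mask)
        assert np.allclose(z[:3], [-1.0, 0.0, 1.0])
        assert z[3] > 3          # masked sample mapped with same affine

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            zscore(np.ones(10))


class TestLowpass:
    def test_dc_gain_unity(self):
        y = lowpass_02hz(np.full(5000, 3.0), fs=FS)
        assert np.allclose(y, 3.0, rtol=1e-3)

    def test_slow_sinusoid_preserved(self):
        t = np.arange(20000) / FS
        x = np.sin(2 * np.pi * 0.02 * t)
        y = lowpass_02hz(x, fs=FS)
        core = slice(2000, -2000)
        assert np.std(y[core]) >= 0.95 * np.std(x[core])

    def test_fast_sinusoid_attenuated(self):
        t = np.arange(5000) / FS
        x = np.sin(2 * np.pi * 2.0 * t)
        y = lowpass_02hz(x, fs=FS)
        assert np.std(y) <= 0.10 * np.std(x)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            lowpass_02hz(np.ones(10), fs=FS)


class TestArtifacts:
    def test_smooth_signal_untouched(self):
        t = _t(2.0)
        x = np.sin(2 * np.pi * 0.01 * t)
        cleaned, mask, _ = remove_artifacts(x)
        assert mask.sum() == 0
        assert np.array_equal(cleaned, x)

    def test_injected_spike_masked_and_interpolated(self, rng):
        x = rng.standard_normal(2000) * 0.1
        x[1000] += 50 * 0.1
        cleaned, mask, _ = remove_artifacts(x, k_mad=8.0)
        assert mask[1000]
        assert mask[998:1003].sum() <= 5   # spike plus one neighbor each side
        assert abs(cleaned[1000]) < 1.0

    def test_infinite_threshold_disables_masking(self, rng):
        x = rng.standard_normal(500)
        x[100] += 100.0
        cleaned, mask, _ = remove_artifacts(x, k_mad=np.inf)
        assert mask.sum() == 0
        assert np.array_equal(cleaned, x)

    def test_heavy_masking_flagged(self, rng):
        x = np.zeros(300)
        x[::3] = 10.0 * rng.standard_normal(100)
        _, _, info = remove_artifacts(x, k_mad=1.0)
        assert info["high_mask_fraction"]


class TestFullChain:
    def _trace(self, rng, gain=1.0):
        t = _t(30.0)
        resp = np.zeros(t.size)
        for onset in range(60, 1700, 60):
            resp[onset * 10:onset * 10 + 10] += 2.0
        m = 0.3 * np.sin(2 * np.pi * 0.003 * t)
        f470 = gain * (_biexp(t, 30, 2400, 8, 400, 100) + resp + m
                       + 0.05 * rng.standard_normal(t.size))
        f405 = gain * (_biexp(t, 20, 2000, 5, 350, 80) + 0.8 * m
                       + 0.05 * rng.standard_normal(t.size))
        return PhotometryTrace(t=t, f470=f470, f405=f405)

    def test_gain_invariance(self):
        rng1 = np.random.default_rng(0)
        rng2 = np.random.default_rng(0)
        z1 = preprocess(self._trace(rng1, gain=1.0)).z
        z2 = preprocess(self._trace(rng2, gain=7.5)).z
        # scaling the raw data perturbs the fit only at float rounding level
        assert np.allclose(z1, z2, atol=1e-4)

    def test_rerun_is_bit_identical(self, rng):
        trace = self._trace(rng)
        a = preprocess(trace)
        b = preprocess(trace)
        assert np.array_equal(a.z, b.z)
        assert a.provenance["order"] == ["remove_artifacts", "fit_bleach",
                                         "isosbestic_correct", "zscore"]

    def test_zscore_contract_on_unmasked_samples(self, rng):
        ct = preprocess(self._trace(rng))
        good = ct.z[~ct.artifact_mask]
        assert abs(good.mean()) < 1e-6
        assert abs(good.std(ddof=1) - 1.0) < 1e-6
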