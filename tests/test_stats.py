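"""Statistical machinery: bootstrap engine oracle equivalence, exact
rank-sum enumeration, Scheirer-Ray-Hare identities, normality gate."""

import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from lcfatigue.stats import (BootstrapSpec, bootstrap_engine, normality_gate,
                             rank_sum, scheirer_ray_hare)


class TestBootstrapEngine:
    def test_identical_units_degenerate(self):
        res = bootstrap_engine(np.array([2.0, 2.0, 2.0]),
                               spec=BootstrapSpec(B=200, seed=0))
        assert res.ci_low == res.ci_high == 2.0

    def test_two_unit_mean_enumeration(self):
        """Units {0,1}: exhaustive mode enumerates the 4 equally likely
        resamples with means {0, 0.5, 0.5, 1}."""
        res = bootstrap_engine(np.array([0.0, 1.0]), exhaustive=True)
        assert res.exhaustive
        assert sorted(res.distribution) == [0.0, 0.5, 0.5, 1.0]

    @pytest.mark.parametrize("values", [
        [0.1, 0.5, 0.9], [1.0, 2.0, 10.0], [0.0, 0.0, 1.0, 1.0]])
    def test_monte_carlo_matches_exhaustive_ci(self, values):
        x = np.array(values)
        ex = bootstrap_engine(x, exhaustive=True)
        mc = bootstrap_engine(x, spec=BootstrapSpec(B=10_000, seed=3),
                              exhaustive=False)
        assert mc.ci_low == pytest.approx(ex.ci_low, abs=0.02)
        assert mc.ci_high == pytest.approx(ex.ci_high, abs=0.02)

    def test_small_b_warns(self):
        res = bootstrap_engine(np.array([0.0, 1.0, 2.0]),
                               spec=BootstrapSpec(B=50, seed=0),
                               exhaustive=False)
        assert res.warnings

    def test_single_unit_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_engine(np.array([1.0]))


class TestRankSum:
    def test_exact_p_matches_full_enumeration_small_samples(self, rng):
        """Exact p agrees with brute-force enumeration over every split for
        several random datasets of total n <= 8 (with and without ties)."""
        for trial in range(10):
            n1, n2 = rng.integers(2, 5), rng.integers(2, 5)
            pooled = np.round(rng.normal(size=n1 + n2), 1)  # induces ties
            xs, ys = pooled[:n1], pooled[n1:]
            ranks = sstats.rankdata(pooled)
            W = ranks[:n1].sum()
            null = [ranks[list(c)].sum()
                    for c in itertools.combinations(range(n1 + n2), n1)]
            null = np.array(null)
            p_expected = min(1.0, 2 * min((null <= W + 1e-9).mean(),
                                          (null >= W - 1e-9).mean()))
            _, p, info = rank_sum(xs, ys, "two-sided")
            assert info["method"] in ("exact", "degenerate")
            assert p == pytest.approx(p_expected, abs=1e-12)

    def test_exact_matches_scipy_without_ties(self, rng):
        xs = rng.normal(size=6)
        ys = rng.normal(loc=1.0, size=7)
        for sided, alt in [("two-sided", "two-sided"), ("less", "less"),
                           ("greater", "greater")]:
            _, p, _ = rank_sum(xs, ys, sided)
            p_scipy = sstats.mannwhitneyu(xs, ys, alternative=alt,
                                          method="exact").pvalue
            assert p == pytest.approx(p_scipy, abs=1e-12)

    def test_normal_approximation_for_large_samples(self, rng):
        xs = rng.normal(size=25)
        ys = rng.normal(loc=0.8, size=30)
        _, p, info = rank_sum(xs, ys, "two-sided")
        assert info["method"] == "normal"
        p_scipy = sstats.mannwhitneyu(xs, ys, alternative="two-sided",
                                      method="asymptotic",
                                      use_continuity=False).pvalue
        assert p == pytest.approx(p_scipy, rel=1e-6)

    def test_all_tied_flags_and_p_one(self):
        _, p, info = rank_sum([1.0, 1.0, 1.0], [1.0, 1.0], "two-sided")
        assert p == 1.0 and info["tie_flag"]


class TestScheirerRayHare:
    def test_constant_data_gives_zero_h(self):
        res = scheirer_ray_hare(np.ones(12),
                                np.repeat(["a", "b"], 6),
                                np.tile(["x", "y", "z"], 4))
        assert all(v == 0.0 for v in res.h.values())

    def test_hand_computed_2x2_on_ranks_1_to_8(self):
        """Values whose ranks are 1..8, split perfectly by factor A
        (A1 = {1,2,3,4}, A2 = {5,6,7,8}), 2 observations per cell:
        SS_A = 4*(2.5-4.5)^2 + 4*(6.5-4.5)^2 = 32, SS_total = 42,
        MS_total = 6, so H_A = 32/6; no ties."""
        values = np.array([10.0, 20, 30, 40, 50, 60, 70, 80])
        fa = np.repeat(["a1", "a2"], 4)
        # B-cells {1,4},{5,8} vs {2,3},{6,7}: column rank means both 4.5
        fb = np.tile(["b1", "b2", "b2", "b1"], 2)
        res = scheirer_ray_hare(values, fa, fb)
        assert res.tie_correction == 1.0
        assert res.h["a"] == pytest.approx(32.0 / 6.0, abs=1e-10)
        assert res.h["b"] == pytest.approx(0.0, abs=1e-10)
        assert res.h["ab"] == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_factor_reduces_to_kruskal_wallis(self, rng):
        values = rng.normal(size=18)
        groups = np.repeat(["g1", "g2", "g3"], 6)
        res = scheirer_ray_hare(values, groups, np.repeat("only", 18))
        kw = sstats.kruskal(values[:6], values[6:12], values[12:])
        assert res.h["a"] == pytest.approx(kw.statistic, abs=1e-10)
        assert res.p["a"] == pytest.approx(kw.pvalue, abs=1e-10)
        assert res.flags

    def test_tie_correction_unity_for_distinct_values(self, rng):
        values = rng.permutation(20).astype(float)
        res = scheirer_ray_hare(values, np.repeat(["a", "b"], 10),
                                np.tile(["x", "y"], 10))
        assert res.tie_correction == 1.0

    def test_invariance_under_monotone_transform(self, rng):
        values = rng.random(24)
        fa = np.repeat(["a", "b"], 12)
        fb = np.tile(["x", "y", "z"], 8)
        r1 = scheirer_ray_hare(values, fa, fb)
        r2 = scheirer_ray_hare(np.exp(5 * values), fa, fb)
        for k in ("a", "b", "ab"):
            assert r1.h[k] == pytest.approx(r2.h[k], rel=1e-12)

    def test_unbalanced_design_flagged(self, rng):
        values = rng.random(10)
        fa = np.array(["a"] * 6 + ["b"] * 4)
        fb = np.array(["x", "y"] * 3 + ["x", "x", "y", "y"])
        res = scheirer_ray_hare(values, fa, fb)
        assert any("unbalanced" in f for f in res.flags)


class TestNormalityGate:
    def test_uniform_samples_usually_rejected(self):
        hits = 0
        for seed in range(40):
            x = np.random.default_rng(seed).uniform(size=500)
            rec = normality_gate([x])
            hits += rec.p_values[0] < 0.05
        assert hits >= 0.8 * 40

    def test_normal_samples_calibrated(self):
        rejections = 0
        n_seeds = 200
        for seed in range(n_seeds):
            x = np.random.default_rng(seed).normal(size=500)
            rejections += normality_gate([x]).p_values[0] < 0.05
        assert 0.02 * n_seeds <= rejections <= 0.08 * n_seeds

    def test_constant_sample_skipped_with_flag(self):
        rec = normality_gate([np.ones(50), np.random.default_rng(0).normal(size=50)])
        assert rec.skipped and rec.skipped[0][1] == "constant sample"
        assert len(rec.p_values) == 1

    def test_nonnormal_data_triggers_nonparametric_choice(self, rng):
        rec = normality_gate([rng.exponential(size=300)])
        assert rec.use_nonparametric
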