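"""Shared statistical machinery.

* a mouse-level bootstrap engine (percentile CIs, exhaustive-enumeration
  mode for very small cohorts),
* the Wilcoxon rank-sum test with exact enumeration for small samples,
* the Scheirer-Ray-Hare rank test (two-factor extension of Kruskal-Wallis),
* a Shapiro-Wilk normality gate that records why nonparametric tests are
  used rather than silently switching.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats


@dataclass
class BootstrapSpec:
    """How to resample: B iterations at the given CI level, unit = mouse."""

    B: int = 10_000
    level: float = 0.95
    unit: str = "mouse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not (0 < self.level < 1):
            raise ValueError("level must be in (0, 1)")


@dataclass
class BootstrapResult:
    distribution: np.ndarray
    ci_low: float
    ci_high: float
    n_units: int
    exhaustive: bool
    n_redrawn: int = 0
    warnings: list = field(default_factory=list)


def bootstrap_engine(per_unit_values: np.ndarray, statistic=None,
                     spec: BootstrapSpec | None = None,
                     exhaustive: bool | None = None) -> BootstrapResult:
    """Resample units (mice) with replacement and collect a statistic.

    ``per_unit_values`` is (n_units,) or (n_units, ...); the default
    statistic is the mean across units (axis 0). With ``exhaustive`` (the
    default for <= 4 units and a scalar-valued statistic) all n^n equally
    likely resamples are enumerated instead of sampled — this is the oracle
    mode the Monte-Carlo path is validated against.
    """
    spec = spec or BootstrapSpec()
    x = np.asarray(per_unit_values, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two units to bootstrap")
    stat = statistic or (lambda v: np.mean(v, axis=0))
    warnings = []
    if spec.B < 100:
        warnings.append("B < 100: CI will be unreliable")

    if exhaustive is None:
        exhaustive = n <= 4 and np.ndim(stat(x)) == 0
    alpha = 1.0 - spec.level
    q = (100 * alpha / 2, 100 * (1 - alpha / 2))

    if exhaustive:
        dist = np.array([stat(x[list(idx)])
                         for idx in itertools.product(range(n), repeat=n)])
        # inverse-CDF quantiles of the exact resampling distribution: the
        # limit the Monte-Carlo percentile estimator converges to
        lo, hi = np.quantile(dist, np.asarray(q) / 100, method="inverted_cdf")
        return BootstrapResult(dist, float(lo), float(hi), n, True,
                               warnings=warnings)

    rng = np.random.default_rng(spec.seed)
    out = []
    n_redrawn = 0
    b = 0
    while b < spec.B:
        idx = rng.integers(0, n, size=n)
        val = stat(x[idx])
        if np.ndim(val) == 0 and not np.isfinite(val):
            n_redrawn += 1
            if n_redrawn > 10 * spec.B:
                raise RuntimeError("statistic undefined on almost all resamples")
            continue
        out.append(val)
        b += 1
    dist = np.asarray(out)
    lo, hi = np.percentile(dist, q, axis=0) if dist.ndim > 1 else \
        np.percentile(dist, q)
    return BootstrapResult(dist, lo, hi, n, False, n_redrawn=n_redrawn,
                           warnings=warnings)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _midranks(values: np.ndarray) -> np.ndarray:
    return sstats.rankdata(values, method="average")


def rank_sum(xs, ys, sided: str = "two-sided") -> tuple[float, float, dict]:
    """Two-sample Wilcoxon rank-sum test on per-mouse values.

    Returns ``(statistic, p, info)`` where the statistic is the rank sum of
    ``xs`` in the pooled midranked sample. For groups of at most 10 each the
    null is enumerated exactly over all assignments of the pooled values
    (valid under ties); otherwise the normal approximation with tie
    correction is used. ``sided`` is 'two-sided', 'less' (alternative:
    xs shifted below ys) or 'greater'.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be nonempty")
    if sided not in ("two-sided", "less", "greater"):
        raise ValueError("sided must be 'two-sided', 'less' or 'greater'")
    pooled = np.concatenate([xs, ys])
    info: dict = {"method": None, "tie_flag": False}
    if np.ptp(pooled) == 0:
        info.update(method="degenerate", tie_flag=True)
        return float(_midranks(pooled)[: xs.size].sum()), 1.0, info

    ranks = _midranks(pooled)
    nx, ny = xs.size, ys.size
    W = float(ranks[:nx].sum())
    info["tie_flag"] = bool(np.unique(pooled).size < pooled.size)

    if nx <= 10 and ny <= 10:
        info["method"] = "exact"
        # Enumerate all C(nx+ny, nx) splits of the pooled ranks.
        all_idx = range(nx + ny)
        stats_null = np.array([ranks[list(c)].sum()
                               for c in itertools.combinations(all_idx, nx)])
        m = stats_null.size
        p_less = np.count_nonzero(stats_null <= W + 1e-9) / m
        p_greater = np.count_nonzero(stats_null >= W - 1e-9) / m
        if sided == "less":
            p = p_less
        elif sided == "greater":
            p = p_greater
        else:
            p = min(1.0, 2.0 * min(p_less, p_greater))
        return W, float(p), info

    info["method"] = "normal"
    N = nx + ny
    mu = nx * (N + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / ((N) * (N - 1))
    var = nx * ny / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        info["tie_flag"] = True
        return W, 1.0, info
    z = (W - mu) / math.sqrt(var)
    if sided == "less":
        p = sstats.norm.cdf(z)
    elif sided == "greater":
        p = sstats.norm.sf(z)
    else:
        p = 2 * sstats.norm.sf(abs(z))
    return W, float(min(1.0, p)), info


# ---------------------------------------------------------------------------
# Scheirer-Ray-Hare


@dataclass
class SRHResult:
    """Rank-based two-way test: H statistics against chi-square references."""

    h: dict               #: effect -> H statistic ('a', 'b', 'ab')
    df: dict
    p: dict
    tie_correction: float
    flags: list = field(default_factory=list)


def _tie_correction(ranks: np.ndarray) -> float:
    N = ranks.size
    _, counts = np.unique(ranks, return_counts=True)
    return 1.0 - np.sum(counts ** 3 - counts) / (N ** 3 - N)


def scheirer_ray_hare(values, factor_a, factor_b) -> SRHResult:
    """Scheirer-Ray-Hare rank test for two crossed factors.

    All N observations are midranked jointly; two-way sums of squares of the
    ranks (unweighted means for unbalanced cells) are divided by
    MS_total = SS_total/(N-1) and by the tie correction
    1 - sum(t^3 - t)/(N^3 - N) to give H statistics referred to chi-square
    distributions with the usual factorial degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (values.shape == fa.shape == fb.shape):
        raise ValueError("values and factor labels must align")
    levels_a = np.unique(fa)
    levels_b = np.unique(fb)
    flags = []
    if levels_a.size < 2 and levels_b.size < 2:
        raise ValueError("need at least two levels in some factor")

    ranks = _midranks(values)
    N = ranks.size
    grand = ranks.mean()
    ss_total = float(np.sum((ranks - grand) ** 2))
    if ss_total == 0:
        df = {"a": max(1, levels_a.size - 1), "b": max(1, levels_b.size - 1)}
        df["ab"] = max(1, df["a"] * df["b"])
        zero = {k: 0.0 for k in ("a", "b", "ab")}
        return SRHResult(h=zero, df=df, p={k: 1.0 for k in zero},
                         tie_correction=1.0, flags=["constant data"])
    ms_total = ss_total / (N - 1)
    D = _tie_correction(ranks)

    # Degenerate factor: reduces to a Kruskal-Wallis on the other factor.
    if levels_a.size < 2 or levels_b.size < 2:
        flags.append("one factor degenerate: reduced to Kruskal-Wallis")
        f = fa if levels_a.size >= 2 else fb
        key = "a" if levels_a.size >= 2 else "b"
        ss = sum(np.sum(f == lv) * (ranks[f == lv].mean() - grand) ** 2
                 for lv in np.unique(f))
        h = float(ss / ms_total / D)
        dfk = int(np.unique(f).size - 1)
        res_h = {"a": np.nan, "b": np.nan, "ab": np.nan}
        res_p = {"a": np.nan, "b": np.nan, "ab": np.nan}
        res_df = {"a": 0, "b": 0, "ab": 0}
        res_h[key] = h
        res_p[key] = float(sstats.chi2.sf(h, dfk))
        res_df[key] = dfk
        return SRHResult(h=res_h, df=res_df, p=res_p, tie_correction=D,
                         flags=flags)

    # Cell means of ranks; unbalanced designs use unweighted means with the
    # harmonic mean cell size.
    cell_means = np.full((levels_a.size, levels_b.size), np.nan)
    cell_n = np.zeros((levels_a.size, levels_b.size), dtype=int)
    for i, la in enumerate(levels_a):
        for j, lb in enumerate(levels_b):
            sel = (fa == la) & (fb == lb)
            cell_n[i, j] = sel.sum()
            if sel.any():
                cell_means[i, j] = ranks[sel].mean()
    if np.any(cell_n == 0):
        flags.append("empty cells: SS computed on available cells")
    balanced = cell_n.min() > 0 and np.all(cell_n == cell_n.flat[0])
    if not balanced and cell_n.min() > 0:
        flags.append("unbalanced design: unweighted-means rank SS")

    if balanced:
        nc = int(cell_n.flat[0])
        row_m = cell_means.mean(axis=1)
        col_m = cell_means.mean(axis=0)
        gm = cell_means.mean()
        ss_a = nc * levels_b.size * np.sum((row_m - gm) ** 2)
        ss_b = nc * levels_a.size * np.sum((col_m - gm) ** 2)
        inter = cell_means - row_m[:, None] - col_m[None, :] + gm
        ss_ab = nc * np.sum(inter ** 2)
    else:
        with np.errstate(invalid="ignore"):
            row_m = np.nanmean(cell_means, axis=1)
            col_m = np.nanmean(cell_means, axis=0)
            gm = np.nanmean(cell_means)
        nz = cell_n[cell_n > 0]
        n_h = nz.size / np.sum(1.0 / nz)
        ss_a = n_h * levels_b.size * np.nansum((row_m - gm) ** 2)
        ss_b = n_h * levels_a.size * np.nansum((col_m - gm) ** 2)
        inter = cell_means - row_m[:, None] - col_m[None, :] + gm
        ss_ab = n_h * np.nansum(inter ** 2)

    df = {"a": levels_a.size - 1, "b": levels_b.size - 1}
    df["ab"] = df["a"] * df["b"]
    h = {k: float(ss / ms_total / D)
         for k, ss in (("a", ss_a), ("b", ss_b), ("ab", ss_ab))}
    p = {k: float(sstats.chi2.sf(h[k], df[k])) for k in h}
    return SRHResult(h=h, df=df, p=p, tie_correction=float(D), flags=flags)


# ---------------------------------------------------------------------------
# Normality gate


@dataclass
class NormalityRecord:
    p_values: list
    all_normal: bool
    alpha: float
    skipped: list = field(default_factory=list)

    @property
    def use_nonparametric(self) -> bool:
        return not self.all_normal


def normality_gate(samples, alpha: float = 0.05) -> NormalityRecord:
    """Shapiro-Wilk test per sample; drives (and logs) the choice of
    nonparametric tests downstream. Samples with n < 3 or zero variance are
    skipped with a flag rather than tested."""
    ps = []
    skipped = []
    for i, s in enumerate(samples):
        s = np.asarray(s, dtype=float)
        if s.size < 3:
            skipped.append((i, "n < 3"))
            continue
        if np.ptp(s) == 0:
            skipped.append((i, "constant sample"))
            continue
        ps.append(float(sstats.shapiro(s).pvalue))
    all_normal = bool(ps) and all(p > alpha for p in ps)
    return NormalityRecord(p_values=ps, all_normal=all_normal, alpha=alpha,
                           skipped=skipped)
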