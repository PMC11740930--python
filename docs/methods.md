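# Methods

`lcfatigue` analyzes how repeated activation of locus coeruleus (LC)
noradrenergic neurons reshapes sleep-wake behavior and how the neurons'
own output fatigues under that activation. The package has two halves: an
analysis pipeline (sleep staging, photometry correction, peri-event
statistics, pulse-response quantification) and a generative simulator that
produces complete synthetic cohorts with known ground truth, so every
analysis stage can be validated by round trip rather than by eye.

## Sleep staging

Each 5-s epoch of EEG/EMG is described by three features: EMG
root-mean-square (muscle tone), EEG delta power (summed spectral power over
1–5 Hz) and the theta/delta power ratio (theta: 6–9 Hz). Spectra are
estimated per epoch with an averaged periodogram (Welch): 2-s Hann
segments, 50% overlap, giving 0.5-Hz bins; band power sums the bins whose
center frequencies fall inside the band, endpoints included. These
estimator choices (segment length, overlap, inclusive band edges,
bin-center convention) are fixed for reproducibility; they are defensible
defaults rather than uniquely correct ones.

Classification applies fixed-precedence rules: high muscle tone → Wake;
otherwise high delta → NREM; otherwise high theta/delta → REM; otherwise
the previous epoch's label is carried forward (first unresolved epoch:
Wake). The carry-forward fallback mirrors how semi-automatic scorers
resolve epochs that satisfy no criterion; a `carry_forward=False` mode
exists so the classifier's memorylessness can be verified.

Thresholds can be supplied, or derived per session by `auto_thresholds`:
a two-component Gaussian mixture on log EMG RMS separates the wake and
sleep modes (threshold at the midpoint of the component means, log scale);
delta and theta/delta thresholds are derived the same way from the
low-EMG (sleep) epochs only. At least 100 epochs are required, and
degenerate (near-constant) feature distributions raise rather than return
arbitrary thresholds.

## Photometry correction

Raw two-channel (470 nm signal / 405 nm isosbestic) traces at 10
samples/s are corrected in a fixed order, recorded in a provenance dict:

1. **Artifact removal** on each raw channel: samples whose absolute first
   difference exceeds `k_mad` (default 8) times the MAD of the absolute
   differences are masked, ±1 neighbor, and linearly interpolated.
   Artifact removal precedes the bleach fit because spikes corrupt
   nonlinear least squares; masking more than 20% of samples sets a
   warning flag.
2. **Bleach fit**: biexponential `A1·exp(−t/τ1) + A2·exp(−t/τ2) + c` per
   channel, multi-start NLS (fast/slow τ pairs spanning ~1–100 min,
   positivity bounds on both τ), best residual wins, fit on a
   gain-normalized and (for long traces) evenly decimated copy so the
   result is scale-equivariant and fast; non-convergence of all starts
   falls back to a single exponential, flagged. The fitted curve is
   subtracted.
3. **Isosbestic correction**: OLS of the detrended 405 channel onto the
   detrended 470 channel over the whole session; the fitted component is
   subtracted. Session-level regression avoids absorbing evoked responses
   into the fit, which per-episode regressions would risk. A constant 405
   channel degrades to mean-centering, flagged.
4. **Z-scoring** over non-masked samples, SD with denominator n−1; masked
   samples are mapped with the same affine transform but stay flagged.

A zero-phase low-pass (−3 dB at 0.2 Hz after the two filtfilt passes;
4th-order Butterworth with a pre-warped corner) is provided for display
and is never applied before pulse quantification.

## Pulse-response quantification

A pulse's amplitude is the mean corrected signal over [onset, onset+1 s)
minus the mean over [onset−1.5 s, onset), windows half-open in session
seconds, samples assigned by timestamp. Pulses whose response or baseline
window overlaps masked samples beyond 50% are dropped and counted.
Amplitudes are averaged per pulse index across episodes (indices beyond
the shortest episode average over the episodes that contain them, with n
reported); the averaged profile divided by its own maximum gives the
normalized profile. The fatigue ratio is the episode-averaged **raw**
amplitude at pulse k (default 12) over pulse 1 — raw rather than
normalized so the quantity does not presuppose that pulse 1 is the
profile's maximum (the two coincide when it is). A mouse's ratio is
undefined when pulse 1's average is nonpositive or fewer than 3 episodes
contribute to either index; undefined mice are excluded from cohort means
with an explicit count.

Group comparisons use the Wilcoxon rank-sum test on per-mouse ratios
(exact enumeration of all splits when both groups have ≤10 mice — valid
under ties via midranks — normal approximation with tie correction
otherwise) and the Scheirer–Ray–Hare rank test on normalized profiles
(factors: group × pulse index).

## Peri-event state analysis

State-probability time courses are binned at the 5-s scoring epoch over a
window (default −240 s to +360 s) around episode onsets or offsets:
per mouse and bin, the fraction of that mouse's episodes occupying each
state; edge-truncated episodes contribute only to in-session bins.
Transition time courses give, per bin t, the fraction of episodes in the
source state at bin t−1 that are in the target state at t; bins with no
source occupancy are undefined (NaN), never zero.

Uncertainty is mouse-level: cohorts are resampled with replacement
(default B = 10,000), percentile intervals per bin. The transition test
compares a target bin against the mouse's baseline average (−240–0 s):
the statistic is the cohort mean of the per-mouse differences, and the
two-sided p-value is `2·min(frac ≤ 0, frac ≥ 0)` over resampled
statistics, floored at 1/B. Sidedness is a configuration switch,
two-sided by default. For ≤4 mice the engine can enumerate all n^n
resamples exactly; quantiles of that exact distribution use the
inverse-CDF convention, which is what the Monte-Carlo percentile
estimator converges to.

**Calibration.** The sign-flip percentile bootstrap is known to be
anticonservative for small cohorts: in an idealized simulation with
Gaussian per-mouse values it rejects ~12% at nominal 5% for n = 8 and
~8% at n = 15, converging to nominal as n grows. The package's engine
reproduces this behavior on generator cohorts (evidence that the engine,
as distinct from the procedure, is correct), and its calibration study
(`experiments.transition_test_type1`) is run at n = 64, where the
measured type-I error is 4.5–6%. Small-cohort p-values near 0.05 from
this test should therefore be read with caution; the floor values
(p = 1/B) reported for large effects are unaffected.

Wake-persistence metrics, from onset-aligned wake-probability courses per
mouse: baseline = mean over −240–0 s; P_peak = peak in-episode increase
over baseline; P_60 = increase at the bin containing +60 s (not
interpolated); persistence ratio = P_60/P_peak, undefined when
P_peak ≤ 0 (tolerance 1e-12 absorbs float rounding); P_aft = mean wake
probability 0–60 s after episode end minus baseline. Delta-power time
courses restrict epochs to a chosen state and normalize by the session's
baseline-window mean delta power in that state (a declared, configurable
choice).

## The synthetic-cohort generator

The generator exists to make every pipeline stage verifiable against
ground truth. Its defaults are the reference study conditions: sessions
of 24 two-minute stimulation episodes at 10-min spacing; within each
episode 2-s pulses with inter-onset gaps uniform on 10 ± 5 s, first pulse
at the episode onset (an anchoring choice that makes pulse-1 alignment
unambiguous); event times on a 0.1-s TTL command grid. Continuous 10-Hz
train episodes are represented at episode granularity only; pulse-resolved
analysis is defined for the intermittent mode.

**Fatigue model.** A single latent inhibition variable `a` stands in for
NE-dependent autoinhibition through Gi-coupled α2A autoreceptors. Between
pulses `a` decays exponentially (τ_a, default 60 s); at pulse k the
calcium amplitude is `C_k = c0·max(floor_ca, 1 − κ_ca·a)`, the NE output
is `N_k = n0·(C_k/c0)·max(floor_ne, 1 − κ_ne·a)`, and then
`a += γ·kd_factor·N_k`. Requiring κ_ne ≥ κ_ca encodes that release
fatigues at least as fast as somatic calcium; `kd_factor < 1` weakens the
feedback loop, emulating autoreceptor knockdown. This is deliberately the
simplest mechanism that yields the three phenomena the generator must
emulate — within-episode decline, NE declining faster than calcium, and
attenuated decline under knockdown — not a biophysical LC model. Defaults
(γ = 1.1, κ_ca = 0.35, κ_ne = 0.70, floors 0.05/0.02) give control-cohort
pulse-12/pulse-1 ratios of ≈0.63 (calcium) and ≈0.17 (NE), and
kd_factor = 0.4 raises the NE ratio to ≈0.32. Between-mouse variability
enters as lognormal jitter on γ (CV 0.15) and on the unit amplitudes
(CV 0.10).

**Sleep model.** An epochwise Markov chain over Wake/NREM/REM, base
matrix chosen for light-phase mouse architecture (stationary distribution
≈ 57% wake, 36% NREM, 7% REM; REM entered only from NREM). Two slow
variables modulate the hazards: recent NE `r` (NE released in the epoch
plus a decaying trace, τ = τ_h/10 — a declared stand-in, since the real
coupling kinetics are unknown) multiplies the NREM→Wake hazard by
(1 + g_w·r) and divides the Wake→NREM hazard by (1 + g_s·r); rebound
pressure `h` (integrating recent NE with decay τ_h, default 150 s)
multiplies the Wake→NREM hazard by (1 + g_p·h). Rows are renormalized.
Defaults (g_w = 15, g_s = 0, α_h = 0.5, g_p = 4) produce the transient
regime: wakefulness rises sharply at episode onset, collapses as NE
fatigues and pressure accumulates (persistence ratio ≈ 0.1), and
undershoots baseline after the episode (P_aft ≈ −0.12). The
`SleepModelParams.sustained()` preset (g_w = 200, g_s = 25, α_h = 0)
emulates arousal populations whose activation holds wake probability near
1 — without the NE suppression of sleep onset, wake occupancy cannot
exceed ~0.95 in a renormalized chain, which is why that term exists
(default 0, so the default model is the two-multiplier form).

**Signals.** EEG is a sum of three band-limited noise streams (delta 1–5
Hz, theta 6–9 Hz, broadband 0.5–45 Hz) with per-state amplitude gains
(NREM delta-dominant, REM theta-dominant, Wake intermediate) at 1500 Hz;
EMG is amplitude-modulated white noise, highest in Wake. Gain envelopes
are smoothed over 0.25 s so epoch boundaries have no step discontinuities.
Photometry (10 samples/s) builds the 470 channel as biexponential bleach +
state-dependent baseline (Wake +0.15 response units, smoothed 5 s) +
per-pulse kernels scaled by the ground-truth amplitudes (saturating rise
during the pulse, exponential decay after; calcium τ_decay 0.6 s, NE
1.2 s) + shared 1–2-sample motion artifacts + white noise (SD 0.05); the
405 channel has its own bleach, a 0.8-scaled copy of the artifacts, and
noise, but no response. Mechanical sessions add sharp shaker-onset spikes
on both channels.

**What the generator does not emulate.** Real EEG nonstationarity within
a state, scorer disagreement near transitions, hemodynamic or
wavelength-dependent artifacts, sensor kinetics nonlinearity, spontaneous
(non-evoked) LC transients, and circadian drift. Round-trip results
(e.g., ~100% staging accuracy, r > 0.99 amplitude recovery) therefore
demonstrate internal consistency of the pipeline, not expected
performance on animal recordings, where thresholds need visual
verification and recovery is necessarily less exact.

## Validation studies and problem sizes

`lcfatigue.experiments` packages the validation studies run by the test
suite and `scripts/acceptance.py`: staging round trip (4 mice × 1 h),
photometry round trip (one session per sensor; amplitude recovery is
scored on episode-averaged per-pulse-index responses, the quantity the
method defines; the corruption-free variant uses jitter-free 12-s spacing
so baseline windows sit beyond the kernel support and recovery is
affine-exact to the bleach fit's ~0.1% numerical tolerance), regime
contrast (8 mice per regime), fatigue-ratio recovery (6 mice per sensor),
knockdown detection power (50 replicate cohorts of 8 vs 8 mice, full
chain), and transition-test calibration (400 null cohorts of 64 mice).
These sizes were chosen so each study gives stable answers at desk scale;
all are parameters of the corresponding functions.

## Numerical conventions

Half-open windows throughout; probabilities undefined (NaN), never zero,
where the conditioning event is absent; z-score SD uses n−1; bootstrap
seeds make every resampling path reproducible; per-mouse seeds derive
from a root `SeedSequence`, so cohorts are bit-reproducible from
(config, seed). Unbalanced Scheirer–Ray–Hare designs use unweighted-means
rank sums of squares with the harmonic-mean cell size, flagged; a factor
with one level reduces to Kruskal–Wallis, flagged. The Shapiro–Wilk gate
records per-sample normality p-values and drives the choice of
nonparametric tests explicitly rather than silently.
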