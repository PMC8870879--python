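# Methods

This note documents the models, defaults and numerical choices behind
`cuffbp`, and what the synthetic-cohort results do and do not say
about real waveform data.

## Signal model and preprocessing

Records are synchronized ECG/PPG/ABP channels at a common sampling
rate (default 125 Hz, the rate of the public ICU waveform dumps this
pipeline is designed around).

**ECG cleaning.** A zero-phase IIR notch (Q = 30) at the configured
powerline frequency (50/60 Hz), then a causal linear-phase FIR
band-pass of even order (default 50, band 0.5–100 Hz). Two practical
constraints are handled explicitly:

* an order-50 kernel cannot realize a 0.5 Hz transition, so the DC
  offset is subtracted before filtering and slow wander is removed by
  a separate zero-phase 4th-order Butterworth high-pass (0.3 Hz
  cutoff, ≥ 90 % suppression of 0.2 Hz wander);
* at 125 Hz the nominal 100 Hz upper edge exceeds the Nyquist
  frequency; the edge is clipped to 0.45·fs with a warning rather
  than failing, since the band's intent (wideband pass) is unaffected.

The FIR group delay is exactly `order/2` samples (0.200 s at order 50,
125 Hz) and is compensated by an integer shift, so filtering is
shape-preserving (zero cross-correlation lag). The even-order
requirement exists precisely so this shift is integral.

**QRS detection** is a Pan–Tompkins detector: 5–15 Hz band-pass,
five-point derivative, squaring, 150 ms moving-window integration,
dual adaptive thresholds with search-back, 200 ms refractory period,
and refinement of each detection to the local raw-ECG maximum. On
synthetic ECG with 5 % additive noise plus drift and powerline
contamination it holds F1 ≥ 0.99 at a ±5-sample tolerance.

**PPG landmarking.** The pulse is denoised with a Daubechies-3
wavelet (soft universal threshold, MAD noise scale) — a smoothing
prior matched to the pulse's shape — and landmarks are located per
beat: systolic peak (window max), foot (backward valley search from
the peak; the foot can precede the R peak because the valley minimum
leads the pulse onset), maximum-slope point (first-derivative max on
the upstroke), dicrotic notch (first local minimum after the peak,
falling back to the second-derivative maximum on weakly pulsatile
beats, flagged), diastolic peak, the first-derivative +/− crossing
interval dT, crest time, and the alternating second-derivative
extrema a–e. All continuous-valued landmarks get sub-sample
refinement by a least-squares parabola over 7 samples; the wide
window averages out wavelet ripple that would bias a 3-point fit in
the shallow inter-pulse valley. On noise-free pulses every landmark
is within one sample of the generator's analytic truth.

**Quality screening** replaces manual record inspection with four
explicit rules (missing fraction > 5 %, any flat segment > 2 s, heart
rate outside 30–200 bpm, ABP outside 30–250 mmHg); a record is
rejected if any rule fires. The thresholds are configuration, not
science; a signal-quality index would be the natural upgrade.

## Features

Per beat: HR; PTT anchored at the PPG maximum-slope point by default
(foot and systolic-peak anchors are config options — the anchor is a
convention, not a measurement, and published definitions differ);
normalized amplitudes and their ratio; systolic and diastolic times;
pulse widths at 1/10, 1/4, 1/3, 1/2, 2/3, 3/4 of the pulse maximum
above the foot baseline, measured with linear interpolation at the
threshold crossings (systolic part, diastolic part, total, and
diastolic/systolic ratio — width at a lower fraction is necessarily
wider, which is asserted per beat); dT and crest time; the
second-derivative ratios b/a, c/a, e/a, (b−e)/a; ECG P/QRS/T
durations and amplitudes. Targets are per-beat ABP extrema.

Beats aggregate to analysis windows (default 60 s, ≥ 5 beats) by the
per-feature **median**, which tolerates isolated detection failures;
a feature missing in more than half a window's beats is masked, and
masked rows are dropped before selection/regression rather than
imputed.

## Dependence measures

All information measures use plug-in (maximum-likelihood) estimates
on discretized variables, base-2 logarithms. Continuous variables are
discretized by equal-frequency binning with
`max(2, floor(sqrt(n)/2))` bins capped at 10 — equal-frequency makes
the marginal entropies near-maximal and comparable across features,
and the √n growth keeps the per-cell counts stable. Joint entropies
are counted sparsely over observed cells, with a guard (10⁷
theoretical cells) against degenerate high-dimensional estimates;
when an MSU over a large set would exceed the guard, the variables
are re-binned to `floor(guard^(1/n))` levels.

Key identities hold exactly and are tested to 10⁻¹²: MSU of two
variables equals SU; total correlation of two variables equals mutual
information; `1/n ≤ H(joint)/ΣH ≤ 1`.

**Plug-in bias matters for thresholds.** For two independent
variables with B bins each, the plug-in MI has expectation
≈ (B−1)²/(2N ln 2) bits — at N = 2000 and B = 10 this floors SU near
0.009. Conversely, a feature carrying a 1/k share of a target built
from k equal independent causes has r = 1/√k and SU ≈ 0.05 at k = 5
*under any binning* (the dependence is genuinely that weak per
feature). The relevance threshold δ must sit between these two
numbers; the default is **δ = 0.03**. At small sample sizes
(N ≲ 300) the bias floor rises above δ, the threshold becomes
nominal, and the SU *ranking* (which is what the fusion step
consumes) carries the selection.

## The hybrid selector

Step 1 ranks features by SU with the (discretized) target and keeps
those ≥ δ (set S₁). Step 2 walks S₁ in SU-descending order; a feature
f is redundant to an already-kept g when `SU(g,f) ≥ p·SU(f,target)`.
The scale p starts at 2.0 and decreases by 0.1 per round to 1.0;
after each round the MSU of the survivors plus the target is
computed and the schedule stops early once it falls to ≤ 0.05
(near-zero multivariate redundancy). The p start value and the stop
value are free parameters (sensitivity: the p schedule mostly matters
for borderline duplicates; with clearly redundant features the first
round at p = 2 already removes them). Every removal is logged
(victim, winner, p, both SU values) so S′ is reconstructible and
auditable. Ties in SU break by column order, making the selector
deterministic and permutation-invariant up to that rule.

ReliefF discretizes the continuous target into 5 quantile classes
(the weight update needs class priors; a regression-native variant
would be the alternative), scales features to [0,1], and for each
instance finds k = 10 Manhattan-nearest hits and, per other class,
k misses, with prior-weighted updates; weights live in [−1, 1]. All
n instances are used by default (estimation reliability grows with
the sample count). An SU pre-ranking keeps the top half of the
features first — this is a cost optimization for wide tables, and it
is compatible with interaction detection as long as interacting
features retain *some* marginal dependence (the planted interaction
is a product of two symmetric features: Pearson-invisible per axis,
but the magnitude channel keeps its marginal SU well above the noise
floor, so pre-ranking retains the pair).

The final feature list is the mean of the two rank positions
(features absent from a ranking get worst-rank + 1), ties broken by
the FC rank then column order, truncated to top-k (default 12). Mean-
rank fusion is the simplest order-level combination that needs no
score calibration between SU units and Relief weights.

## Penalized regression

The objective is `SSE + λ·α·Σ|βⱼ| + λ·(1−α)/2·Σβⱼ²` on internally
standardized features and a centered target — a single shared penalty
scale λ, so α = 0 is exactly ridge and α = 1 exactly lasso. With
standardized columns the coordinate update is
`βⱼ ← S(ρⱼ, λα/2)/(n + λ(1−α)/2)`, where ρⱼ is the partial residual
correlation; this scaling convention makes the closed-form oracles
exact: OLS at λ = 0, `(XᵀX + (λ/2)I)⁻¹Xᵀy` at α = 0, and the
soft-threshold formula on zero-mean orthonormal designs at α = 1
(all verified to 10⁻⁶, plus a cross-check against an independent
solver via the penalty-scale mapping λ = 2n·α_sklearn).

The solver runs in covariance form (Gram matrix and correlation
vector) with an optional compiled inner loop; the penalized objective
is recorded every sweep and asserted non-increasing on every fit.
Convergence: max coefficient change < 10⁻⁷ or 10⁴ sweeps (best
iterate kept with a warning). Cross-validation over λ (50 log-spaced
points, 10⁻³…10³) and α ∈ {0, 0.25, 0.5, 0.75, 1} uses seeded
shuffled K-folds (default 10) and warm starts along the descending-λ
path (the objective is convex, so warm starting changes arrival
time, not the solution); the CV search uses a looser tolerance
(10⁻⁵, 2·10³ sweeps) than the final refit. The residual variance
estimate is SSE/(n − m) with m = nonzero coefficients + 1.

## Evaluation

Errors are predicted − reference (mmHg). BHS cumulative percentages
(|e| ≤ 5/10/15 mmHg) grade against A: 60/85/95, B: 50/75/90,
C: 40/65/85, else D; the grade is monotone under error shrinkage.
The AAMI thresholds (|mean| ≤ 5, SD ≤ 8 mmHg) come from that standard
— not from the grading grid — and are reported as advisory.

## The synthetic generator

**Waveforms.** ECG beats are sums of Gaussian bumps for P/Q/R/S/T at
fixed physiologic offsets; the R schedule is exact and strictly
periodic per record (first R at 0.4 s). The PPG pulse is a systolic
bump plus a delayed, smaller diastolic bump — guaranteeing exactly
one dicrotic notch between them — plus a broad base component that
keeps the inter-pulse valley curved, so the pulse foot is a unique,
well-conditioned minimum (a flat valley would make sub-sample foot
location ill-posed for any detector). Lead-in and tail pulses keep
the train periodic at the record edges so the analytic landmark
truth applies to the first and last beats too. Pulse onsets lag each
R peak by the subject's PTT (uniform in 0.15–0.35 s); heart rate is
uniform in 60–100 bpm; pulse-shape parameters jitter ±10 % per
subject. ABP is the same pulse rescaled per beat (foot to foot) to
[DBP, SBP], so each beat's sampled extremes equal the true values
exactly.

**BP model.** Per record,
`SBP = 55 + 9/PTT + 0.35·HR + 25·W50 + 15·exp(−W10/0.3) + ε`,
`DBP = 40 + 4/PTT + 0.15·HR + 10·W50 + 8·exp(−W10/0.3) + ε`,
with ε ~ N(0, 3 mmHg) by default and W50/W10 the pulse's true
fractional widths (seconds). The coefficients were chosen once to
span physiologic ranges (SBP ≈ 105–165, DBP ≈ 60–90 mmHg over the
covariate ranges); each target carries exactly one nonlinear term so
that SU-versus-Pearson differences must manifest. The 1/PTT and
exponential-width terms also mean a linear model in the *measured*
features is deliberately misspecified by a curvature-sized amount.

**Planted tables.** The target is a weighted sum of components, each
standardized to unit variance analytically (so equal effect sizes
mean equal contribution shares): raw uniform columns (linear),
symmetric transforms g ∈ {x², sin(πx), |x|} of uniform columns
(each has zero population correlation with its source), optionally a
product pair x·x′ (an XOR-like sign structure, Pearson-invisible per
axis), plus N(0, 0.3) target noise. Redundant columns are copies
plus Gaussian noise at 1.0× the source SD (r ≈ 0.71 to the source —
typical of genuinely collinear physiological features); this level is
deliberate: with much smaller copy noise the original's and copy's SU
with the target become statistically indistinguishable at n = 2000
and the choice between them is a coin flip, which no ranking-based
filter can resolve. Noise columns are independent uniforms. Column
roles are recorded so recovery is scorable.

All randomness derives from a single seed through
`numpy.random.SeedSequence`; identical configurations are
bit-identical, and a full pipeline run writes every artifact with the
config hash (two runs with the same config produce byte-identical
artifact files).

## Problem sizes

The reference cohort is 300 subjects × 60 s at 125 Hz with 3 mmHg BP
noise, split 70/30 train/test by window; selection and CV run on the
training split only. Monte-Carlo properties use 50 seeds (selector
recovery and nonlinear retention at n = 2000) and 20 seeds (ReliefF
interaction, QRS F1). On this cohort the held-out RMSE sits within
1–2 mmHg of the irreducible noise and the error distribution reaches
BHS grade A for both targets.

## What the synthetic results do not show

The generator has constant heart rate and PTT within a record, no
respiratory modulation, motion artifacts, arrhythmias or sensor
saturation, Gaussian noise only, and a BP model whose true covariates
are (nonlinear transforms of) the measured features. Passing the
synthetic suite therefore validates the *algorithms* — detector
accuracy against known truth, selector recovery of planted structure,
solver correctness, metric arithmetic — not clinical performance.
Real-data accuracy depends on waveform quality, inter-subject
physiology and calibration drift, none of which are modeled here.

## Known limitations

* ReliefF's target discretization loses within-class BP ordering; a
  regression-native Relief variant would avoid the choice of class
  count (default 5).
* The dicrotic-notch fallback (second-derivative maximum) marks the
  beat but the downstream features do not distinguish fallback
  notches from true local minima.
* Equal-frequency binning with the √n rule is a sensible default but
  not optimal for heavily skewed features; bin count is configurable
  and the δ discussion above describes how the threshold should move
  with it.
* The quality screen is rule-based; records that are subtly corrupted
  (e.g. intermittent PPG clipping) can pass.
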