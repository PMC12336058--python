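# Methods

This note documents the models implemented in `hemilat`, the parameters
that matter, the numerical choices behind them, and what the synthetic
data do and do not establish about real recordings.

## 1. Preprocessing of bilateral CBFV recordings

A session consists of synchronized left/right middle-cerebral-artery
blood-flow-velocity traces (cm/s) plus a trial schedule: per trial, a 3 s
instruction screen, 20 s of covert word generation and 15 s of rest
(16 trials by default). The chain runs in this fixed order:

1. **Downsampling** (100 → 25 Hz by default) by non-overlapping block
   averaging. The block mean is an implicit anti-alias filter; the rate
   ratio must be an integer and block means are exactly testable.
2. **Epoching** into 38 s windows from 10 s before the instruction onset
   to 5 s after the end of word generation ([−10, +28] s). The placement
   of the 5 s remainder after the task preserves the full pre-stimulus
   window; trials whose window leaves the recording are dropped and
   counted.
3. **Spike/dropout detection.** Bounds are the (1e−4, 0.9999) quantiles
   per channel over *all* epoched samples of the session — per-epoch
   quantiles at that level would be meaningless at ~950 samples.
   Within an epoch: one outlying sample is replaced by the epoch-channel
   mean computed *excluding* the outlier (including a 10× spike in its
   own replacement would defeat the correction); two or more outliers
   across both channels exclude the epoch. Note a structural property of
   strict quantile bounds on continuous data: the most extreme one or two
   order statistics per tail are always flagged, so even clean sessions
   lose an occasional epoch. This mirrors the published procedure and is
   harmless downstream (the epoch count enters the SE and the t quantile).
4. **Normalization** of each channel to a session mean of 100 over kept
   epochs, removing dependence on insonation angle and vessel diameter.
   The session-level (not per-epoch) mean keeps the later 60–140 % band
   interpretable; per-epoch normalization would force every epoch mean to
   100 and largely disable that filter.
5. **Heart-cycle integration.** Cardiac cycles are delimited by diastolic
   troughs (local minima ≥ 0.33 s apart, i.e. ≤ 180 bpm); each cycle is
   replaced by its time-mean at the cycle midpoint and linearly
   re-interpolated. Trough positions are refined to sub-sample precision
   by parabolic interpolation and the cycle mean is a fractional-endpoint
   trapezoidal integral; without this, cycle means are biased first-order
   in the mismatch between the cardiac period and the sample grid
   (≈0.8 % for a 1.2 Hz pulse at 25 Hz). Windows with fewer than two
   troughs pass through unchanged with a warning flag.
6. **Baseline correction** by subtracting the mean of the 8 s of rest
   preceding the instruction screen, per epoch and channel, yielding Δ%
   units. Subtraction (not division) keeps the laterality index on the
   Δ% scale on which group means of ≈ −3 are reported in this literature.
7. **Range rejection**: any epoch whose *pre-baseline-subtraction*
   normalized values fall strictly below 60 or above 140 is excluded.
   60.0 and 140.0 themselves are kept.

Every stage treats the hemispheres identically, so swapping the input
channels swaps the outputs exactly at every stage; the kept-epoch count
is non-increasing through QC. Manual (visual-inspection) exclusions are
supported only as an externally supplied trial list, never automated.

## 2. Laterality index and classification

Per kept epoch, the LI is the mean of (right − left) over the period of
interest — 3 s after word-generation onset to the end of the task
(17 s; half-open window on the sample grid). The session LI is the mean
of per-epoch LIs, the SE their sample standard deviation (n−1) over √n,
and the 95 % CI uses the Student-t quantile t₀.₉₇₅,ₙ₋₁ by default. With
~14–16 epochs per session the t interval attains the nominal 95 %
coverage; the fixed 1.96 multiplier (available as `ci_method="normal"`)
covers only ≈93 % at these epoch counts, which would distort the
bilateral-classification rate the interval exists to calibrate. Negative
LIs mean leftward dominance. Classification: BLD iff the CI contains
zero, else LLD/RLD by sign; the dichotomous label is the sign alone, with
an exactly-zero LI resolved deterministically to "left" and logged.
Split-half LIs use the odd/even parity of the 1-based design position
(not the post-QC position), so QC exclusions shrink a half rather than
re-shuffling it; an empty half is NaN, not an error.

## 3. Reliability battery

* **ICC(A,1)** — two-way ANOVA (subjects × sessions), absolute
  agreement, single measurement:
  `(MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))`, k = 2.
  The F test of zero ICC uses the McGraw–Wong construction
  `F = MS_R / (a·MS_C + b·MS_E)` with weights from the *estimated* ICC
  and Satterthwaite-approximated denominator df — hence the generally
  non-integer df₂. Absolute agreement (unlike consistency) penalizes an
  additive between-session shift, which is the point for test–retest
  bias.
* **Cohen's κ** over the fixed label universe {LLD, BLD, RLD} (absent
  categories contribute zero marginals), with Z = κ/SE₀ from the Fleiss
  large-sample null variance and a one-sided p for κ > 0.
* **Percentage agreement** per subgroup, stored exact and displayed
  rounded to integer percent.
* **Bland–Altman**: differences are session1 − session2 (direction fixed
  for determinism); limits of agreement are mean ± 1.96·SD (literal
  1.96, matching how limits of agreement are conventionally defined).
* **Cutoff sweep** over |LI| ≤ c for c = 0.0, 0.1, …, 1.5: proportion
  bilateral in session 1, and among those, the proportion also bilateral
  in session 2 (missing when no session-1 bilaterals exist). The
  session-1 proportion is monotone in c by construction.
* **Group tests**: Welch t (Satterthwaite df) and paired t via
  scipy; one-sided Mann–Whitney U reporting the first sample's U (the
  convention R prints as W), exact-enumeration p for tie-free samples
  with min(n₁,n₂) ≤ 8 and n₁+n₂ ≤ 20, otherwise the normal approximation
  with tie and continuity corrections; effect size r = |z|/√(n₁+n₂)
  (the most common convention — other definitions of r exist and are not
  distinguished in most reports). Spearman's ρ uses average ranks and the
  t approximation; constant input yields NaN rather than an error.

## 4. Visual half-field asymmetry

Per-hemifield accuracy over non-control trials; the asymmetry is the
normalized difference `(acc_LVF − acc_RVF) / (acc_LVF + acc_RVF)`,
bounded in [−1, 1] and negative for a right-visual-field advantage
(left-hemisphere dominance), matching the Doppler sign. The normalized
difference is chosen over the raw difference because the bounded index
supports absolute-value group comparisons; whether published asymmetries
normalize by the sum is not always stated, so this is a documented
package convention. A reaction-time variant (same formula on per-field
median RTs of correct trials, sign-inverted) is provided as a secondary
index only. Central fixation-control trials never enter either index.

## 5. Bootstrap laterality index for ROI statistic maps

Thresholds are 20 equally spaced levels from 0 (exclusive) to the
maximum statistic across both hemisphere ROIs, so the ladder is invariant
to positive rescaling. A threshold is admissible when at least one side
retains ≥ 5 supra-threshold voxels; a side with none contributes zero
activation, so one-sided maps reach the ±1 endpoints exactly. Per
admissible threshold, 100 resamples of size ⌈0.25·n⌉ are drawn with
replacement per side; all 100² pairwise values of
`(ΣR − ΣL)/(ΣR + ΣL)` are formed, the central 50 % (25 % trimmed per
tail) is averaged, and the overall index is the threshold-weighted mean
of the per-threshold trimmed means. All counts, ratios and the seed are
configurable; the defaults follow the standard configuration of the
established bootstrap-LI approach for statistic maps. Sign convention:
−1 = left-only activation (the mirror of the (L−R)/(L+R) orientation
some toolboxes print), for consistency with the Doppler LI.

A consequence worth knowing: when the two sides' value distributions are
well separated, the weaker side drops out above some threshold and the
per-threshold index saturates at ±1 there, so the threshold-weighted
overall index is more extreme than the naive sum-ratio
`(mR − mL)/(mR + mL)`. The sum-ratio is the right oracle only at
thresholds below the bulk of both distributions, and the tests check it
exactly there.

## 6. Synthetic data: what is emulated

A simulated channel is
`base · (1 + pulse(t)) · (1 + response(t)/100 + noise(t))` with

| parameter | default | meaning |
|---|---|---|
| base velocity | 60 cm/s | mean MCA flow velocity |
| heart rate | 70 bpm | cardiac fundamental |
| pulsatility | 0.25 | systolic peak over mean, pulse shape ((1+cosθ)/2)² |
| response amplitude | 4 % | bilateral task-evoked rise |
| response ramp / fall | 3 s / 5 s | linear rise after task onset, decay after task end |
| noise | 1 % SD, AR(1) φ=0.9 | per-channel measurement noise |
| spikes / dropouts | 0 /min | 80 ms stretches × 2.5 or × 0.15 |

Laterality enters as an antisymmetric split of the response amplitude:
left = A − d/2, right = A + d/2 with d = trait + state, so the
pipeline's expected LI is d. The pulse shape has a single trough per
cycle by construction, so cycle segmentation is well defined. The ramp
completes before the POI begins and the plateau spans it, so the POI
mean of the response shape is exactly 1 and recovery tests are sharp up
to one known bias: session-mean normalization divides each channel by
(1 + its own mean response), which attenuates recovered LIs by ≈4 % of
their value (trait −3 is recovered near −2.88). This is a property of
the published normalization itself, not of the generator.

Retest cohorts draw one trait per subject from a two-mode Gaussian
mixture — a dominant left mode (mean −3 Δ%, SD 1, weight 0.85) and a
near-zero minority (mean 0, SD 0.5, weight 0.15) — chosen to mimic the
qualitative shape of empirical verbal-fluency LI distributions; these
are synthetic conventions, not empirical estimates. State offsets are
independent Normal(0, state_sd) per session with state_sd = 0.8 Δ% by
default (no empirical anchor exists for this variance). The
measurement-noise contribution to the LI is characterized empirically by
a no-state calibration run rather than derived analytically: AR(1)
noise passed through the nonlinear QC chain has no clean closed form.
With trait SD σ_t, state SD σ_s and measured noise SD σ_m, the expected
test–retest ICC is σ_t²/(σ_t² + σ_s² + σ_m²), which the cohort tests
verify at n = 200.

What the generator does **not** emulate: heart-rate variability and
waveform change within a session, respiratory and vasomotor oscillations,
probe-repositioning differences between sessions, insonation-depth/gain
effects, and any dependence of state on physiology (e.g. hormonal
cycles). Passing tests therefore demonstrate correctness of the analysis
chain and its calibration under the stated generative model, not
robustness to every artifact class of real Doppler recordings.

## 7. Problem sizes and tolerances

The classifier-calibration check uses 1000 null sessions (binomial
95 % band around 0.95 at that n); trait recovery averages 50 sessions
with a ±0.3 Δ% band that absorbs the normalization attenuation; the
cohort ICC check uses 200 subjects × 2 sessions against the closed-form
ratio with a ±0.06 band (≈2 Monte-Carlo SDs of the ICC estimator at that
n). Exact identities (normalization mean 100, baseline mean 0, channel
swap antisymmetry, bootstrap endpoints, scale invariance) are asserted to
1e−9 or exact equality. Degenerate inputs have deterministic outcomes:
zero-variance data raise for ICC and paired t, constant input yields NaN
for Spearman and undefined κ for a single shared category, an exactly
zero LI dichotomizes to "left" with a log message, and empty split
halves are NaN.

## 8. Known limitations

* The heart-cycle integrator assumes a single dominant trough per cycle;
  strongly dicrotic waveforms could split cycles (mitigated by the
  0.33 s minimum inter-beat distance).
* ICC significance follows the estimated-weight Satterthwaite F test;
  alternative ICC software that tests with null weights (F = MS_R/MS_E)
  reports integer df and slightly different p-values.
* The Mann–Whitney effect size r is one of several conventions.
* The bootstrap LI's threshold ladder and weighting are one standard
  configuration; variants (unweighted means, different trims) exist and
  are exposed through the config rather than auto-selected.
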