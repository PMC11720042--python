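# Methods

This note documents the models, numerical choices and known limitations of
the `swaylift` pipeline. Everything quantitative stated here is computed by
the test suite or the analysis scripts; nothing is asserted that the code
does not measure.

## 1. Synthetic lifting sessions

### Signal model

The generator emulates a protocol of eight subjects each performing two
sessions of twenty lifts with a lumbar IMU sampling at 128 Hz: a No-Risk
session (light load at 2.5 lifts/min) and a Risk session (heavy load at
6 lifts/min). A session is a quiet-standing baseline (white noise,
sd = 0.05 m/s²) into which one burst per lift is inserted at the session
cadence. A burst is band-limited Gaussian noise (Butterworth 1–5 Hz,
zero-phase), normalised to unit variance, shaped by a Hann envelope of the
lift's duration (uniform 2–4 s), and scaled per channel. This is
deliberately a *signal* model, not a biomechanical one: the downstream
stages only require realistic amplitude and frequency structure plus exact
ground-truth lift boundaries, which a physics simulation would not provide
any better.

The class effect encodes the observation that heavier loads shift the
body + load centre of mass and increase sway, chiefly anteroposteriorly:
the AP (z-axis) sway scale is 1.0 for No-Risk vs 1.8 for Risk (separation
δ = 1.8), the ML (y-axis) scale 0.5 vs 0.65. The x-axis carries baseline
noise only and is never consumed. Per-lift and per-subject log-normal
amplitude jitter (σ = 0.03 each) add heterogeneity. With these defaults the
default pipeline's gradient-boosting CV accuracy lands near 0.9 (measured
0.85–0.93 across seeds in the acceptance tests), which is the regime this
kind of study reports; δ and the noise parameters are exposed in
`SimulationConfig` for sensitivity work.

Two generator choices matter for interpretation:

- **Burst band 1–5 Hz.** The analysis retains 1–50 Hz at segmentation and
  0–5 Hz in the stabilogram; a burst with energy outside that intersection
  would lose a realisation-dependent energy share to the filters, inflating
  within-class variance with pure filter-overlap noise that has no
  real-world analogue. Keeping the burst inside the retained band makes the
  class separation parameter mean what it says.
- **No gravity component.** Signals are generated about zero; the 1 Hz
  high-pass removes DC in any case.

### What passing tests do and do not show

The generator produces stationary, independent lifts with a known
class-conditional scale difference. Passing the recovery and classification
tests therefore shows the *pipeline machinery* is correct and that an
AP-dominant dispersion effect of plausible size is detectable end-to-end.
It does not show that real lifting produces such an effect, nor does the
generator model fatigue accumulation across lifts, inter-lift posture
drift, or sensor artefacts (saturation, axis misalignment).

## 2. RNLE module

The multiplier formulas follow the NIOSH Applications Manual in metric
units: HM = 25/H (H clamped to ≥ 25 cm, zero beyond 63 cm),
VM = 1 − 0.003·|V − 75|, DM = 0.82 + 4.5/D (D ≤ 25 cm → 1), AM = 1 −
0.0032·A, FM from the frequency × duration × (V < 75 / V ≥ 75) lookup
table, CM from the coupling × V table. Geometry outside the applicability
domain zeroes the affected multiplier (task "not recommended") and sets a
warning flag rather than raising, matching standard RNLE practice.
Between tabulated frequencies FM is linearly interpolated (documented
choice; tables are printed at integer rates but protocols use rates like
2.5 lifts/min). LI = 1 maps to No-Risk because risk is defined by LI
strictly greater than 1.

The two scenario presets fix V = 50, D = 70, A = 0, good coupling, ≤ 1 h,
with (2.5 lifts/min, 7 kg) and (6 lifts/min, 15 kg). The horizontal reach
is not part of the protocol description, so H = 30 cm is recorded as an
explicit assumption; it yields LI = 0.50 and 1.28, close to the sessions'
nominal indices 0.5 and 1.3. The female load variants (5 kg / 10 kg) give
lower indices under the same geometry — the heavy female task comes out
below LI = 1 — so the presets use the male loads; reproducing the nominal
indices for all load variants would need per-variant geometry the protocol
does not state.

## 3. Lift segmentation

Detection runs on the z-axis: zero-phase 4th-order Butterworth band-pass
1–50 Hz (forward–backward, so burst centres are not delayed),
rectification, and a 2nd-order Savitzky–Golay filter with a 1501-sample
frame (11.7 s at 128 Hz) as the activity envelope. ROIs are maximal runs
with envelope ≥ threshold; runs shorter than 0.5 s are discarded as
spikes, and runs touching either end of the recording are discarded as
partial lifts. Indices are 0-based, half-open.

The per-subject threshold is calibrated by scanning 512 candidates between
the envelope's 5th and 99.9th percentiles and taking the midpoint of the
widest contiguous plateau of candidates that yield the expected lift
count. The plateau rule makes the calibration reproducible and insensitive
to small envelope perturbations; if no candidate achieves the expected
count the calibration fails loudly, reporting the achievable counts.

**Known limitation — boundary widening.** The 11.7 s smoothing frame is
roughly four times the lift duration, so each burst's envelope bump is
substantially wider than the burst. Count recovery is exact (100 % of
recordings across 20 seeds at default noise, both cadences), but detected
boundaries sit ~2.5–3 s outside the true burst edges at the calibrated
threshold, and no global threshold can do much better: thresholds high
enough to tighten one burst's boundaries fragment or drop weaker bursts.
Downstream, each feature window therefore includes a margin of quiet
baseline, which dilutes per-window feature contrast somewhat (detected-ROI
CV accuracy runs a few points below ground-truth-ROI accuracy in the
analysis scripts). A shorter frame would localise boundaries better; the
long frame is kept as the method's stated configuration.

## 4. Sway statistics

Windows are cut from the 1–50 Hz filtered z/y signals, resampled to 20 Hz
by polyphase rational resampling (anti-aliasing built in), low-passed with
a zero-phase 3rd-order Butterworth at 5 Hz, and de-meaned per channel —
in that order. Segments shorter than 1 s are rejected (frequency measures
would be meaningless).

The fourteen statistics follow the classical centre-of-pressure formulary,
transplanted to COM acceleration (units m/s² for distances). Four readings
needed care:

- **MDIST_AP / MDIST_ML are means of absolute deviations.** The naive
  directional form (mean of the signed channel) is identically zero on a
  de-meaned channel; the absolute form is the one the COP literature
  defines. This is the single most consequential correction in the module.
- **RDIST is max(RD) − min(RD)** — the range of the resultant-distance
  series, as the formulary prints it, although prose descriptions often
  say "maximum distance between any two points on the path" (a different
  quantity, the path diameter). The printed range is implemented.
- **SA takes the absolute shoelace sum.** Without the absolute value the
  enclosed-area rate can come out negative (orientation-dependent),
  violating its semantics.
- **Spectral moments** are μk = Σ (m·Δf)^k · G(m) over the one-sided
  periodogram of the mean-removed RD series, with the DC bin excluded; a
  residual mean would otherwise dominate μ0. The PSD is a plain boxcar
  periodogram (no Welch averaging — unbiased bin frequencies matter more
  here than variance reduction); Δf = fs/N. An optional band restriction
  (e.g. the 0.15–5 Hz quiet-stance convention) is available but off by
  default.

MF = TOTEX/(2π·MDIST·T) is the equivalent rotation frequency;
CF = sqrt(μ2/μ0) the RMS frequency; DF = sqrt(1 − μ1²/(μ0·μ2)) ∈ [0, 1] by
Cauchy–Schwarz. Degenerate inputs (zero MDIST or zero spectral power)
raise a dedicated error instead of returning NaNs.

Verification is dual-route: every statistic is checked against an
independent direct-summation implementation (explicit DFT matrix, scalar
loops) on 1000 random stabilograms at 1e-9 relative tolerance, plus closed
forms on canonical paths (circle: MDIST = r, MV = 2πr/T₀, SA = πr²/T₀,
MF = revolutions/T; single-tone RD: CF = f₀, DF = 0) and invariance
properties (scaling degree 1/2/0, channel-negation symmetry).

## 5. Classification harness

Stratified 10-fold CV with shuffled, seeded fold assignment. Per fold:
optional feature selection, max-min normalisation for kNN/MLP/SVM
(min/max fitted on the training fold only, evaluation values not clipped,
constant features mapped to 0), fit, predict. Test-fold predictions are
pooled into a single confusion matrix and the metrics are computed from
that pooled matrix — not averaged per fold — so one matrix accounts for
every instance exactly once; AUCROC is the tie-aware rank statistic on the
pooled positive-class scores. **No-Risk is the positive class** throughout
(sensitivity = No-Risk recall). Undefined metrics (empty denominator) are
NaN, never 0.

Backward feature elimination is the greedy wrapper: repeatedly drop the
feature whose removal maximises the same classifier's CV accuracy, stop
when every removal strictly decreases it, return the best subset
encountered (ties between candidate removals break by feature name;
accuracy ties between subsets prefer the smaller). By default BFE runs
once on the full table before CV — simple and matching the single-workflow
setup such studies describe — with a `nested` flag that re-runs it inside
each training fold for leakage-free estimates; the default's selection
bias is acknowledged.

Battery specifics:

- GB (93 trees, depth 7, lr 0.186), DT (min 6 records/leaf), RaF (57
  trees, depth 20, min node 7), kNN (k = 3), MLP (2 × 43 neurons, 109
  iterations) via scikit-learn; hyperparameters are the fixed
  pre-optimised values, no search is performed.
- SVM: polynomial kernel with gamma 1.971, coef0 1.033; the fitted kernel
  power 1.99 is rounded to degree 2 (the implementation requires an
  integer degree).
- XGB (21 leaves, eta 0.212, gamma 0, lambda 100, 59 bins) behind an
  optional dependency, wrapped in a string-label adapter.
- PNN is implemented directly as a dynamic-decay-adjustment RBF network
  (theta− = 0.113, theta+ = 0.509, ≤ 131 epochs): units are committed per
  class when no same-class unit activates above theta+, and
  opposite-class unit radii shrink until their activation at the sample
  falls below theta−.
- Rotation forest is implemented directly (10 trees, 3 disjoint feature
  subsets, per-subset PCA on a 75 % subsample, full rotation matrix per
  tree) since only default parameters are specified for it.

## 6. Information-gain ranking

Continuous features are discretised by equal-frequency (quantile) binning,
10 bins by default (the discretisation any IG implementation must choose
but reports rarely state); bin counts differ by at most one for distinct
values and ties never straddle a bin edge, which makes IG invariant to
strictly monotone feature transforms. IG is the label-entropy reduction in
bits; shares are percentages of the summed IG over all 14 features,
sorted descending with alphabetical tie-break.

## 7. Problem sizes and determinism

The test suite and acceptance script run at the study's own scale — 8
subjects × 2 sessions × 20 lifts (320 windows) per dataset — which keeps a
full simulate–extract–classify round under ~5 s. Statistical acceptance
checks use 10 simulation replicates for effect recovery and AP-dominance
(mean GB CV accuracy ≥ 0.85 at δ = 1.8; these checks run without BFE,
whose selection step adds minutes without changing the outcome) and 3
replicates for the class-null control (accuracy within 3σ binomial of
0.5 when δ = 1). All randomness flows through explicit integer seeds:
identical configuration + seed reproduces bit-identical datasets, folds
and reports.

## 8. Known limitations

- Boundary widening by the long envelope frame (§3) — count-exact but
  boundary-approximate segmentation.
- The generator's lifts are i.i.d. within a session; no fatigue trend,
  no cross-lift correlation, no gyroscope/magnetometer channels.
- BFE outside CV (the default) optimistically biases reported accuracy;
  use `nested=True` for unbiased estimates.
- The RNLE presets depend on an assumed horizontal reach (§2); composite
  or variable lifting-index extensions are out of scope.
- PNN and rotation forest are faithful but minimal implementations of
  their algorithms, not feature-complete ports of any particular toolkit.
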