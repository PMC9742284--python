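# Methods notes

This document records the modeling choices, parameter conventions and known
limitations of the `fnirscreen` pipeline, in the order data flows through it.

## Synthetic cohorts

Clinical resting-state prefrontal recordings of the kind this pipeline
targets are generally not shareable, so the package includes a forward model
that generates cohorts with the statistical structure the analysis assumes.
The generator is first-class, tested code: its defaults define the study
conditions used throughout the test suite.

**Probe geometry.** The device's true channel coordinates are proprietary;
`generate_layout` places the 48 deep-sampling channels on an
arbitrary-but-fixed 6×8 forehead grid (2.0 cm column pitch, 1.5 cm row
pitch, ±0.1 cm seeded jitter) with the 3.35 cm source–detector separation
recorded on every channel. Topographic maps are therefore reproducible but
not anatomically registered.

**Latent hemodynamics.** Per channel, the latent Δ[HbO] signal is a sum of

- a low-frequency resting oscillation, 0.02–0.2 Hz band-limited Gaussian
  noise normalized to unit sample SD and scaled by `lf_amplitude`
  (default 1.0 µmol/L = 1e-3 mM) — the carrier of the group effect;
- a Mayer wave (~0.1 Hz sinusoid, 0.4e-3 mM) and a respiratory component
  (~0.25 Hz, 0.3e-3 mM), with per-channel random phases;
- slow drift (linear ramp plus a 0.003 Hz sinusoid, 1e-3 mM scale).

Δ[HbR] is modeled as −0.4 × Δ[HbO] (anticorrelated, smaller), which is all
the analysis needs since features use oxyhemoglobin only.

**Amplitude variability.** Each subject carries a lognormal amplitude factor
(log-SD 0.25) shared across channels, and each channel an independent
lognormal factor (log-SD 0.45). These values were chosen once as a
plausible decomposition of between-subject versus between-channel
physiological variability at rest; they produce cohort-level classification
accuracies in the high-0.8s at a 3× group effect, i.e. discriminable but not
trivially separable.

**Group effect.** `effect_size` is the control-over-patient amplitude ratio
of the low-frequency component in the `informative_channels` subset (default
four channels in the upper-left, i.e. left-dorsolateral, region of the
grid). Implementation-wise the control amplitude is multiplied by
`effect_size`, so `effect_size = 1` makes the groups exchangeable in
distribution, matching the reduced resting prefrontal amplitude observed in
patients while keeping the null case exact. Four informative channels is the
deliberate default because the analysis sweep is expected to peak near that
subset size.

**Optical level.** The latent concentrations are pushed through the same
forward modified Beer–Lambert equations the preprocessing stage inverts
(shared coefficient object), then cardiac pulsation (~1.05–1.2 Hz, amplitude
2e-3 OD with slow envelope, slightly weaker at 850 nm) is added at the
optical-density level, followed by motion artifacts: Poisson-timed events
(default 0.5/min), each a 1–3 s square pulse or decaying spike applied
across channels with amplitude 8–20× the channel's background OD standard
deviation — deliberately large enough that the windowed-SD/MAD rule must
catch them.

**Metadata.** Patient neuropsychological scores (MMSE, Boston Naming Test,
Verbal Memory total recall) are drawn from normal distributions with
cohort-plausible means and spreads, rounded to integers and clipped to test
ranges; roughly 4 of 21 patients carry no scores (untestable), and controls
carry only MMSE. Scores are redrawn if a test would not admit a well-defined
median split. These are plausibility fixtures only — no claim of
distributional fidelity.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: anatomical geometry and photon transport, spatial
correlation between neighboring channels, heteroscedastic or non-Gaussian
physiological noise, slow non-stationarity across the session, and any
coupling between neuropsychological scores and the hemodynamic effect. Tests
against this generator validate the *pipeline's statistical machinery*
(calibration, recovery, invariances), not clinical effect sizes.

## Preprocessing

**MBLL coefficients.** Extinction coefficients default to
literature-tabulated values at 780/850 nm (in mM⁻¹cm⁻¹: HbO 0.735/1.058,
HbR 1.030/0.691) with DPF 6.0 at both wavelengths and L = 3.35 cm. All are
exposed in `MBLLCoefficients`, so device-specific constants can be
substituted; the 2×2 system is inverted once and applied pointwise.
Concentrations are in mM throughout.

**Filter.** Zero-phase (forward–backward) Butterworth, order 3 per pass,
0.01–0.5 Hz. The family and order are a package choice (standard in fNIRS;
zero phase keeps window SDs undistorted). The double pass roughly squares
the magnitude response, giving ≥ 20 dB at 1 Hz. Because the finite-length
transient of the 0.01 Hz pole leaves a small DC residue, the filtered series
are explicitly re-centered to zero mean — consistent with DC lying outside
the passband; filtered-series means are exactly 0 by construction.

**Artifact rule conventions.** Sample SDs (n−1 denominator) in
nonoverlapping windows of floor(10 s × fs) samples (81 at 8.138 Hz); the
trailing partial window is discarded. The MAD is the *raw* median absolute
deviation — no 1.4826 normal-consistency factor — because the 4.5×MAD
threshold is self-referential to whatever MAD convention accompanies it; the
consistency-scaled variant is available via `scaled_mad=True`. The
comparison is strictly greater-than, so an SD sitting exactly at
median + 4.5×MAD survives. A channel whose window SDs have zero MAD is
degenerate: nothing is excluded and a warning is logged. Detection runs on
the filtered Δ[HbO] series by default (`source="hbr"` is available); the
time series itself is never interpolated or repaired — outlier windows are
only excluded from feature averaging. At least 3 complete windows are
required.

## Features and labels

The session feature is the *mean of retained window SDs* per channel (not
one SD over concatenated retained samples); the two differ slightly and the
windowed mean matches the episode-averaged reading of the activation
definition. Features use HbO only by default; HbR is computable via the same
code path but is not assembled into matrices by default.

Median splits of patient scores use a strict greater-than rule by default
(`tie_rule="greater_equal"` available) — with integer scores, tied medians
make the two rules produce different split sizes, so the rule is recorded in
the matrix's `label_definition` provenance. Missing channels (all windows
excluded) are a hard error by default; column-median imputation is opt-in.

Standardization is column-wise z-scoring with mean and sample SD taken from
the training rows only. Inside cross-validation folds, zero-SD training
columns are scaled by 1 (they carry no information on that fold); at the
user-facing `standardize` level a zero-SD column is an error naming the
channel.

## Chi-squared ranking

Continuous features are discretized into 10 nominal quantile bins; duplicate
quantile edges collapse, and bins are merged with their smaller adjacent
neighbor until every expected cell count is ≥ 1 (stopping at 2 bins). The
Pearson chi-squared test of independence (no continuity correction) against
the binary label gives p, and the priority score is ln(1/p), floored at the
smallest positive float so scores stay finite. Quantile binning makes scores
invariant under strictly increasing transforms of a feature. With 39
subjects and ~10 bins the per-cell expected counts are small (~2), so
individual p-values lean on the chi-squared approximation; the test suite
checks null calibration at a sample size where the approximation is sound
(200 subjects) rather than asserting exact uniformity at cohort scale.

Ranking is descending by score with ties broken by ascending channel id.
Two leakage policies exist: `per-fold` (default; ranking recomputed on each
training fold, leakage-safe) and `full-matrix` (rank once on all subjects
before CV — mirrors common filter-then-classify practice but lets the filter
see test subjects). The mode is recorded in provenance.

## Classification and evaluation

Linear-kernel SVM with box constraint C = 1 on standardized features; no
hyperparameter search, no kernel scaling heuristics. Cross-validation is
5-fold over subjects, repeated 20 times with fresh partitions; since each
subject is one row, train and test never share a subject. Folds are
stratified by default: with 21/18 subjects an unstratified 5-fold can
produce a single-class test fold, leaving specificity undefined.

The partitioner is a deliberate reimplementation rather than a library
splitter: subjects are shuffled once per repetition and dealt round-robin to
folds within each stratum, with strata identified by their index sets (not
label values) and processed in order of smallest member. This makes the
partition invariant under swapping the two class labels, so sensitivity and
specificity exchange *exactly* under label swap — a property the test suite
audits bitwise.

Confusion counts are pooled over the folds of a repetition; sensitivity
TP/(TP+FN) and specificity TN/(TN+FP) are exact ratios per repetition, and
summaries report the median ± SD over repetitions. The k-sweep shares each
repetition's partition across all subset sizes, so per-k curves are paired
samples. Per-fold standardization is applied in both ranking modes.

## Permutation statistics

Each permutation repetition reshuffles the label vector uniformly over
subjects (class counts preserved by construction) and reruns one repetition
of the identical CV pipeline — fresh partition, per-fold standardization and
per-fold ranking — across the k-range. The default of 20 permutation
repetitions is symmetric with the 20 actual CV repetitions, which enables
the paired comparison.

Actual and null distributions are compared per k and metric with a
two-sided Wilcoxon signed-rank test pairing by repetition index. The exact
conditional null distribution of the positive-rank sum (midranks, zeros
dropped) is enumerated by dynamic programming for up to 25 informative
pairs; beyond that a tie-corrected normal approximation is used. Bonferroni
correction multiplies by the number of subset sizes × 2 metrics (capped at
1). A two-sample Kolmogorov–Smirnov variant is available via `test="ks"`
for users who prefer an unpaired comparison.

## Topographic maps

Per-channel scalars are interpolated with piecewise-linear barycentric
interpolation on the Delaunay triangulation of channel positions: exact at
channels, bounded by the channel value range, and masked (never
extrapolated) outside the convex hull. A cubic interpolant would be smoother
but overshoots; linearity was chosen for bound preservation.

## Orchestration and reproducibility

A single run seed is split into independent streams for cohort generation,
CV partitions and permutations, so stages can be rerun in isolation and a
fixed configuration reproduces every output bit-identically. Each CSV output
carries a header comment with a hash of the analysis-relevant configuration
(output paths excluded), and `provenance.json` records the config, seed,
derived seeds, package version and per-subject excluded-window counts.

## Problem sizes used in the test suite

Statistical tests run at deliberately chosen scales: null-calibration of the
chi-squared scores at 200 subjects × 200 features; chance-level and
permutation-null checks on full 39-subject cohorts; the type-I calibration
over 100 null cohorts with 100-s recordings, k ∈ {2, 4, 8}, 10 CV
repetitions and 10 permutations per cohort; parameter recovery over 20
cohorts at the full 300-s recording length (recovery of the informative
subset is sensitive to feature estimation noise, which shrinks with the
number of retained windows). These sizes are the package's own choices for
a deterministic, reasonably fast suite.

## Known limitations

- No motion *correction* (wavelet/spline) or short-separation regression —
  artifacts are excluded, not repaired; Mayer waves are deliberately left in
  the passband.
- Chi-squared binning at n ≈ 39 yields approximate p-values; scores are used
  as a ranking statistic, and exact reproduction of any particular score
  magnitude on real data is not claimed.
- The SVM mirrors a fixed-box-constraint linear classifier; other
  implementations' kernel-scale heuristics may differ in small numeric ways.
- Whether artifact screening should run on optical or concentration signals
  is ambiguous in common practice; this pipeline screens filtered Δ[HbO]
  (configurable).
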